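"""scikit-learn style estimator façade over the divergence-point analysis.

`DivergencePointAnalysis` follows the sklearn estimator contract: all
configuration lives in ``__init__`` parameters (inspectable through
``get_params``/``set_params``, clonable, usable inside pipelines and grid
search), ``fit`` takes a binned fixation table and computes the analysis,
and results land in trailing-underscore attributes.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dpa import BootstrapConfig, DivergenceResult, OnsetCriterion, bootstrap_divergence
from .io import BIN_MS, ValidationError, validate_binned_table
from .preprocessing import CONTRASTS, SUBSETS, proportion_curves

__all__ = ["DivergencePointAnalysis"]


class DivergencePointAnalysis(BaseEstimator):
    """Estimate a fixation divergence point with a stratified bootstrap.

    Parameters
    ----------
    contrast : {"targets_vs_distractors", "compatible_vs_incompatible"}
        Which object-set contrast to analyse.
    subset : str or None
        Trial subset (``all_gendered``, ``gender_match``, ``gender_mismatch``,
        ``neutral``); ``None`` uses the contrast's default.
    denominator : {"pair", "trial"}
        Proportion denominator: looks to A / looks to (A or B), or / trials.
    alpha : float
        Per-bin two-sided significance level of the one-sample t-test.
    run_length_bins : int
        Minimum number of consecutive significant bins declaring an onset
        (10 bins = 500 ms at the default bin width).
    window : (int, int)
        Analysis window in ms relative to verb onset, left-closed.
    n_boot : int
        Number of bootstrap resamples.
    ci_level : float
        Coverage of the percentile confidence interval.
    resampling : {"trial", "per_bin"}
        Whole-trial (default) or independent per-bin stratified resampling.
    random_state : int or None
        Seed for the bootstrap resampler.

    Attributes
    ----------
    curves_ : ProportionCurves
        Observed per-participant and grand-average proportion curves.
    bin_stats_ : pandas.DataFrame
        Per-bin t statistic, p value, and participant count.
    onset_ms_ : int or None
        Observed divergence point (left bin edge, ms after verb onset).
    bootstrap_onsets_ : ndarray
        Detected onsets across resamples.
    detection_rate_ : float
        Fraction of resamples with a detected onset.
    mean_divergence_ms_ : float or None
        Mean of the detected bootstrap onsets.
    ci_low_ms_, ci_high_ms_ : int or None
        Percentile interval bounds (on the bin lattice).
    result_ : DivergenceResult
        The full result object.

    Examples
    --------
    >>> from gazedpa.simulate import SimulationConfig, build_design, simulate_gaze
    >>> cfg = SimulationConfig(seed=7)
    >>> table, truth = simulate_gaze(build_design(cfg), cfg)
    >>> est = DivergencePointAnalysis(n_boot=200, random_state=0).fit(table)
    >>> est.onset_ms_ is not None
    True
    """

    def __init__(
        self,
        contrast: str = "targets_vs_distractors",
        subset: str | None = None,
        denominator: str = "pair",
        alpha: float = 0.05,
        run_length_bins: int = 10,
        window: tuple[int, int] = (0, 1500),
        n_boot: int = 2000,
        ci_level: float = 0.95,
        resampling: str = "trial",
        random_state: int | None = None,
    ) -> None:
        self.contrast = contrast
        self.subset = subset
        self.denominator = denominator
        self.alpha = alpha
        self.run_length_bins = run_length_bins
        self.window = window
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.resampling = resampling
        self.random_state = random_state

    # -- validation -------------------------------------------------------
    def _check_params(self) -> tuple[OnsetCriterion, BootstrapConfig]:
        if self.contrast not in CONTRASTS:
            raise ValidationError(
                f"contrast must be one of {sorted(CONTRASTS)}, got {self.contrast!r}"
            )
        if self.subset is not None and self.subset not in SUBSETS:
            raise ValidationError(
                f"subset must be one of {sorted(SUBSETS)} or None, got {self.subset!r}"
            )
        if not isinstance(self.random_state, (type(None), numbers.Integral)):
            raise ValidationError("random_state must be an int or None")
        criterion = OnsetCriterion(
            alpha=self.alpha,
            run_length_bins=int(self.run_length_bins),
            window=tuple(self.window),
        )
        boot = BootstrapConfig(
            n_boot=int(self.n_boot),
            ci_level=self.ci_level,
            resampling=self.resampling,
            seed=None if self.random_state is None else int(self.random_state),
        )
        return criterion, boot

    # -- estimator API ----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "DivergencePointAnalysis":
        """Run the full analysis on a binned fixation table.

        ``X`` is the long-format table (see ``gazedpa.io.BINNED_COLUMNS``);
        ``y`` is ignored and present for API compatibility.
        """
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a binned fixation table (DataFrame)")
        criterion, boot = self._check_params()
        X = validate_binned_table(X)
        result: DivergenceResult = bootstrap_divergence(
            X,
            self.contrast,
            criterion=criterion,
            boot=boot,
            subset=self.subset,
            denominator=self.denominator,
        )
        self.curves_ = proportion_curves(
            X,
            self.contrast,
            subset=self.subset or CONTRASTS[self.contrast].default_subset,
            denominator=self.denominator,
        )
        self.result_ = result
        self.bin_stats_ = result.bin_stats
        self.onset_ms_ = result.onset_ms
        self.bootstrap_onsets_ = result.bootstrap_onsets
        self.detection_rate_ = result.detection_rate
        self.mean_divergence_ms_ = result.mean_divergence_ms
        self.ci_low_ms_ = result.ci_low_ms
        self.ci_high_ms_ = result.ci_high_ms
        self.n_participants_ = int(result.bin_stats["n"].max())
        return self

    def predict(self, X: pd.DataFrame | None = None) -> float | None:
        """Return the fitted mean bootstrap divergence (ms), or ``None`` when
        no resample detected an onset. ``X`` is ignored: the divergence point
        is a property of the fitted dataset."""
        check_is_fitted(self, "result_")
        return self.mean_divergence_ms_

    def summary(self) -> dict:
        """Fitted result as a plain dict (JSON-serialisable)."""
        check_is_fitted(self, "result_")
        return self.result_.to_dict()
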