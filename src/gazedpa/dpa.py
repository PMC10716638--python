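"""Bootstrap divergence-point analysis.

The procedure has three steps. (1) At every 50 ms bin in the analysis
window, participant-level fixation proportions are tested against 0.50 with
a two-sided one-sample t-test (df = n_participants - 1). (2) The divergence
point is the left edge of the first bin opening a run of at least
``run_length_bins`` consecutive significant bins (p < alpha). (3) The
sampling distribution of that onset comes from a non-parametric bootstrap:
trials are resampled with replacement within participant x image-type
strata, each resampled trial carrying its whole time course, and steps 1-2
are recomputed per replicate. The estimate is the mean of the detected
onsets and the CI the percentile interval of their distribution; replicates
without a detectable onset are excluded from both and reported through
``detection_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BIN_MS, ValidationError, bin_grid
from .preprocessing import (
    CONTRASTS,
    ContrastSpec,
    ProportionCurves,
    proportion_curves,
    select_trials,
)

__all__ = [
    "OnsetCriterion",
    "BootstrapConfig",
    "DivergenceResult",
    "pointwise_tests",
    "detect_onset",
    "bootstrap_divergence",
    "run_contrast",
]


@dataclass(frozen=True)
class OnsetCriterion:
    """Run-length onset rule: first of >= ``run_length_bins`` consecutive
    bins with p < ``alpha`` inside ``window`` (ms relative to verb onset)."""

    alpha: float = 0.05
    run_length_bins: int = 10
    window: tuple[int, int] = (0, 1500)
    bin_ms: int = BIN_MS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.run_length_bins < 1:
            raise ValidationError("run_length_bins must be >= 1")
        grid = bin_grid(self.window, self.bin_ms)
        if len(grid) < self.run_length_bins:
            raise ValidationError(
                f"window {self.window} holds {len(grid)} bins, fewer than the "
                f"run length {self.run_length_bins}"
            )

    @property
    def grid(self) -> np.ndarray:
        return bin_grid(self.window, self.bin_ms)


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings for the divergence bootstrap.

    ``resampling="trial"`` (default) resamples whole trials within
    participant x image-type strata, preserving each trial's temporal
    autocorrelation; ``"per_bin"`` resamples trials independently at every
    bin (the strict reading of per-time-point categories).
    """

    n_boot: int = 2000
    ci_level: float = 0.95
    resampling: str = "trial"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        if self.resampling not in ("trial", "per_bin"):
            raise ValidationError(
                f"resampling must be 'trial' or 'per_bin', got {self.resampling!r}"
            )


@dataclass
class DivergenceResult:
    """Observed and bootstrap divergence estimates for one contrast."""

    contrast: str
    subset: str
    bin_stats: pd.DataFrame  # columns: bin, t, p, n
    onset_ms: int | None
    bootstrap_onsets: np.ndarray  # detected onsets only, ms
    n_boot: int
    detection_rate: float
    mean_divergence_ms: float | None
    ci_low_ms: int | None
    ci_high_ms: int | None
    ci_level: float = 0.95

    @property
    def diverged(self) -> bool:
        return self.detection_rate > 0

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "subset": self.subset,
            "onset_ms": self.onset_ms,
            "n_boot": self.n_boot,
            "detection_rate": self.detection_rate,
            "mean_divergence_ms": self.mean_divergence_ms,
            "ci_low_ms": self.ci_low_ms,
            "ci_high_ms": self.ci_high_ms,
            "ci_level": self.ci_level,
            "bin_stats": self.bin_stats.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# step 1: pointwise tests
# ---------------------------------------------------------------------------

def _t_test_matrix(values: np.ndarray, mu0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-sample t-tests along the first axis, NaN-aware.

    ``values`` has shape (n_participants, ...); returns (t, p, n) arrays of
    the trailing shape. Bins with n < 2 get NaN t and p. Zero-variance bins
    follow the degenerate-limit convention: t = +/-inf, p = 0 when the mean
    differs from mu0; t = 0, p = 1 when it equals mu0.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    vals0 = np.where(mask, values, 0.0)
    n = mask.sum(axis=0)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = vals0.sum(axis=0) / np.maximum(n, 1)
        ss = (np.where(mask, values - mean, 0.0) ** 2).sum(axis=0)
        var = ss / np.maximum(n - 1, 1)
        se = np.sqrt(var / np.maximum(n, 1))
        t = np.where(ok, (mean - mu0) / se, np.nan)
    p = np.full(np.shape(t), np.nan)
    df = np.maximum(n - 1, 1)
    finite = ok & np.isfinite(t)
    p = np.where(finite, 2.0 * stats.t.sf(np.abs(np.where(finite, t, 0.0)), df), p)
    # degenerate zero-variance bins: exact null -> (0, 1); otherwise (+/-inf, 0)
    zero_sd = ok & np.isclose(np.sqrt(var), 0.0)
    if np.any(zero_sd):
        with np.errstate(invalid="ignore"):
            null_mean = np.isclose(mean, mu0)
            t = np.where(zero_sd & null_mean, 0.0, t)
            p = np.where(zero_sd & null_mean, 1.0, p)
            t = np.where(zero_sd & ~null_mean, np.sign(mean - mu0) * np.inf, t)
            p = np.where(zero_sd & ~null_mean, 0.0, p)
    return t, p, n


def pointwise_tests(curves: ProportionCurves, mu0: float = 0.5) -> pd.DataFrame:
    """Two-sided one-sample t-test of participant means against ``mu0`` at
    every bin. Returns a DataFrame with columns bin, t, p, n; bins with
    fewer than two defined participant values carry NaN statistics."""
    wide = curves.by_participant.pivot(index="participant", columns="bin", values="p_a")
    values = wide.to_numpy(dtype=float)
    t, p, n = _t_test_matrix(values, mu0)
    out = pd.DataFrame(
        {"bin": wide.columns.to_numpy(), "t": t, "p": p, "n": n.astype(int)}
    )
    if (out["n"] < 2).all():
        raise ValidationError("no bin has two or more testable participants")
    return out


# ---------------------------------------------------------------------------
# step 2: run-length onset detection
# ---------------------------------------------------------------------------

def _first_run_start(sig: np.ndarray, run_length: int) -> np.ndarray:
    """Index of the first run of >= run_length consecutive True per row.

    ``sig`` is a boolean (n_rows, n_bins) matrix; returns -1 where no such
    run exists.
    """
    n_rows, n_bins = sig.shape
    if n_bins < run_length:
        return np.full(n_rows, -1, dtype=np.int64)
    # window sums via cumulative sums: full[i] == run_length means a run
    # covers bins [i, i + run_length)
    c = np.concatenate(
        [np.zeros((n_rows, 1), dtype=np.int64), np.cumsum(sig, axis=1)], axis=1
    )
    full = c[:, run_length:] - c[:, :-run_length]  # (n_rows, n_bins-run_length+1)
    hit = full == run_length
    any_hit = hit.any(axis=1)
    idx = np.where(any_hit, np.argmax(hit, axis=1), -1)
    return idx


def detect_onset(
    pvals: pd.DataFrame | Sequence[float],
    criterion: OnsetCriterion = OnsetCriterion(),
    bins: Sequence[int] | None = None,
) -> int | None:
    """Left edge (ms) of the first bin opening a run of at least
    ``run_length_bins`` consecutive bins with p < alpha, or ``None``.

    Accepts either the DataFrame from :func:`pointwise_tests` or a plain
    p-value sequence with matching ``bins``. Only bins inside the
    criterion's window are considered; untestable (NaN) bins break runs.
    """
    if isinstance(pvals, pd.DataFrame):
        bins_arr = pvals["bin"].to_numpy()
        p = pvals["p"].to_numpy(dtype=float)
    else:
        if bins is None:
            raise ValidationError("bins must accompany a raw p-value sequence")
        bins_arr = np.asarray(list(bins))
        p = np.asarray(list(pvals), dtype=float)
    grid = criterion.grid
    order = {b: i for i, b in enumerate(bins_arr)}
    missing = [b for b in grid if b not in order]
    if missing:
        raise ValidationError(f"p values missing for window bins {missing[:5]}")
    pw = p[[order[b] for b in grid]]
    sig = (pw < criterion.alpha) & ~np.isnan(pw)
    idx = _first_run_start(sig[None, :], criterion.run_length_bins)[0]
    return None if idx < 0 else int(grid[idx])


# ---------------------------------------------------------------------------
# step 3: stratified bootstrap
# ---------------------------------------------------------------------------

@dataclass
class _ParticipantArrays:
    """Per-trial numerator/denominator matrices for one participant."""

    a: np.ndarray          # (n_trials, n_bins) looks to set A
    n: np.ndarray          # (n_trials, n_bins) informative looks (A or B)
    strata: np.ndarray     # (n_trials,) stratum code per trial


def _build_arrays(
    table: pd.DataFrame,
    spec: ContrastSpec,
    subset: str,
    denominator: str,
) -> tuple[list[_ParticipantArrays], np.ndarray]:
    """Reduce the long table to per-participant (trial x bin) count matrices."""
    sel = select_trials(table, subset)
    in_a = spec.set_a(sel).to_numpy()
    in_b = spec.set_b(sel).to_numpy()
    fx = sel["fixated"].to_numpy()
    work = pd.DataFrame(
        {
            "participant": sel["participant"].to_numpy(),
            "trial": sel["trial"].to_numpy(),
            "item_type": sel["item_type"].to_numpy(),
            "bin": sel["bin"].to_numpy(),
            "a": fx * in_a,
            "ab": fx * (in_a | in_b),
        }
    )
    agg = work.groupby(["participant", "trial", "item_type", "bin"], sort=True).agg(
        a=("a", "sum"), ab=("ab", "sum")
    ).reset_index()
    bins = np.unique(agg["bin"].to_numpy())
    out: list[_ParticipantArrays] = []
    for _, grp in agg.groupby("participant", sort=True):
        wide_a = grp.pivot(index="trial", columns="bin", values="a")
        wide_n = grp.pivot(index="trial", columns="bin", values="ab")
        trial_itype = grp.drop_duplicates("trial").set_index("trial")["item_type"]
        strata = pd.Categorical(trial_itype.loc[wide_a.index]).codes
        a = wide_a.to_numpy(dtype=float)
        if denominator == "pair":
            nmat = wide_n.to_numpy(dtype=float)
        elif denominator == "trial":
            nmat = np.ones_like(a)
        else:
            raise ValidationError(f"unknown denominator {denominator!r}")
        out.append(_ParticipantArrays(a=a, n=nmat, strata=np.asarray(strata)))
    return out, bins


def _bootstrap_proportions(
    arrays: list[_ParticipantArrays],
    n_boot: int,
    rng: np.random.Generator,
    resampling: str,
) -> np.ndarray:
    """Bootstrap p_a per replicate: shape (n_boot, n_participants, n_bins)."""
    n_bins = arrays[0].a.shape[1]
    out = np.empty((n_boot, len(arrays), n_bins))
    for pi, pa in enumerate(arrays):
        numer = np.zeros((n_boot, n_bins))
        denom = np.zeros((n_boot, n_bins))
        for code in np.unique(pa.strata):
            rows = pa.strata == code
            a_g, n_g = pa.a[rows], pa.n[rows]
            n_trials = int(rows.sum())
            probs = np.full(n_trials, 1.0 / n_trials)
            if resampling == "trial":
                w = rng.multinomial(n_trials, probs, size=n_boot)  # (n_boot, n_trials)
                numer += w @ a_g
                denom += w @ n_g
            else:  # per-bin: independent trial resampling at every bin
                w = rng.multinomial(n_trials, probs, size=(n_boot, n_bins))
                numer += np.einsum("rbt,tb->rb", w, a_g)
                denom += np.einsum("rbt,tb->rb", w, n_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, pi, :] = np.where(denom > 0, numer / np.where(denom > 0, denom, 1), np.nan)
    return out


def _quantile_on_lattice(x: np.ndarray, q: float) -> int:
    """Percentile that always returns an observed (lattice) value."""
    return int(np.quantile(x, q, method="closest_observation"))


def bootstrap_divergence(
    table: pd.DataFrame,
    contrast: ContrastSpec | str,
    criterion: OnsetCriterion = OnsetCriterion(),
    boot: BootstrapConfig = BootstrapConfig(),
    subset: str | None = None,
    denominator: str = "pair",
    mu0: float = 0.5,
) -> DivergenceResult:
    """Full three-step divergence-point analysis of one contrast.

    Returns the observed per-bin statistics and onset plus the bootstrap
    onset distribution, its mean, and the percentile CI. When no replicate
    detects an onset the result carries ``onset_ms=None``-style fields and
    ``detection_rate`` 0 rather than raising.
    """
    spec = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    subset = subset or spec.default_subset

    curves = proportion_curves(table, spec, subset=subset, denominator=denominator)
    bin_stats = pointwise_tests(curves, mu0=mu0)
    observed_onset = detect_onset(bin_stats, criterion)

    grid = criterion.grid
    # only window bins feed the bootstrap; earlier bins matter for the
    # observed curves/statistics above but not for onset detection
    arrays, bins = _build_arrays(
        table[table["bin"].isin(grid)], spec, subset, denominator
    )
    col_of = {b: i for i, b in enumerate(bins)}
    missing = [b for b in grid if b not in col_of]
    if missing:
        raise ValidationError(f"table lacks window bins {missing[:5]}")
    win_cols = np.array([col_of[b] for b in grid])

    rng = np.random.default_rng(boot.seed)
    props = _bootstrap_proportions(arrays, boot.n_boot, rng, boot.resampling)
    t, p, n = _t_test_matrix(np.swapaxes(props, 0, 1), mu0)  # (n_boot, n_bins)
    pw = p[:, win_cols]
    sig = (pw < criterion.alpha) & ~np.isnan(pw)
    idx = _first_run_start(sig, criterion.run_length_bins)
    detected = idx >= 0
    onsets = grid[idx[detected]]

    detection_rate = float(detected.mean())
    if detected.any():
        alpha_tail = (1.0 - boot.ci_level) / 2.0
        mean_div = float(onsets.mean())
        ci_low = _quantile_on_lattice(onsets, alpha_tail)
        ci_high = _quantile_on_lattice(onsets, 1.0 - alpha_tail)
    else:
        mean_div = ci_low = ci_high = None
    return DivergenceResult(
        contrast=spec.name,
        subset=subset,
        bin_stats=bin_stats,
        onset_ms=observed_onset,
        bootstrap_onsets=np.asarray(onsets, dtype=int),
        n_boot=boot.n_boot,
        detection_rate=detection_rate,
        mean_divergence_ms=mean_div,
        ci_low_ms=ci_low,
        ci_high_ms=ci_high,
        ci_level=boot.ci_level,
    )


def run_contrast(
    table: pd.DataFrame,
    contrast_name: str,
    subset: str | None = None,
    criterion: OnsetCriterion = OnsetCriterion(),
    boot: BootstrapConfig = BootstrapConfig(),
    denominator: str = "pair",
) -> DivergenceResult:
    """Run one named analysis (select -> curves -> tests -> onset -> bootstrap)."""
    if contrast_name not in CONTRASTS:
        raise ValidationError(
            f"unknown contrast {contrast_name!r}; expected one of {sorted(CONTRASTS)}"
        )
    try:
        return bootstrap_divergence(
            table,
            contrast_name,
            criterion=criterion,
            boot=boot,
            subset=subset,
            denominator=denominator,
        )
    except ValidationError as exc:
        raise ValidationError(f"[{contrast_name}/{subset or 'default'}] {exc}") from exc
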