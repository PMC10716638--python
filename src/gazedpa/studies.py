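"""Simulation studies: error rates and parameter recovery of the procedure.

These run many synthetic experiments through the exact analysis path a real
dataset would take, measuring the onset rule's false-alarm rate under a true
null and the bootstrap's ability to recover a known divergence point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np
import pandas as pd

from .dpa import BootstrapConfig, OnsetCriterion, bootstrap_divergence, detect_onset, pointwise_tests
from .preprocessing import proportion_curves
from .simulate import SimulationConfig, build_design, simulate_gaze

__all__ = ["observed_onset", "type_one_error_study", "recovery_study"]


def observed_onset(
    table: pd.DataFrame,
    contrast: str,
    subset: str | None = None,
    criterion: OnsetCriterion = OnsetCriterion(),
) -> int | None:
    """Onset from the observed data only (no bootstrap): curves -> pointwise
    t-tests -> run-length detection."""
    curves = proportion_curves(table, contrast, subset=subset)
    return detect_onset(pointwise_tests(curves), criterion)


def _experiment_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(2 * n).reshape(n, 2) % (2**31 - 1)


def type_one_error_study(
    n_experiments: int,
    config: SimulationConfig | None = None,
    contrast: str = "targets_vs_distractors",
    subset: str = "all_gendered",
    criterion: OnsetCriterion = OnsetCriterion(),
    seed: int = 0,
) -> float:
    """Fraction of null experiments in which an onset is (falsely) detected.

    The default configuration is the study design with ``asymptote_pref``
    forced to 0.5 and no egocentric effect — a true null for every contrast.
    """
    config = config or SimulationConfig()
    config = replace(config, asymptote_pref=0.5, egocentric_effect=0.0)
    hits = 0
    for ds, gs in _experiment_seeds(seed, n_experiments):
        design = build_design(config, seed=int(ds))
        table, _ = simulate_gaze(design, config, seed=int(gs), validate=False)
        if observed_onset(table, contrast, subset=subset, criterion=criterion) is not None:
            hits += 1
    return hits / n_experiments


def recovery_study(
    n_experiments: int,
    config: SimulationConfig | None = None,
    contrast: str = "targets_vs_distractors",
    subset: str = "all_gendered",
    criterion: OnsetCriterion = OnsetCriterion(),
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap divergence estimates across replicated experiments.

    Each experiment is generated with a known ``true_onset_ms`` and analysed
    with the full three-step bootstrap. Returns one row per experiment with
    the observed onset, mean divergence, CI bounds, and detection rate.
    """
    config = config or SimulationConfig(true_onset_ms=500, asymptote_pref=0.75)
    rows = []
    for i, (ds, gs) in enumerate(_experiment_seeds(seed, n_experiments)):
        design = build_design(config, seed=int(ds))
        table, truth = simulate_gaze(design, config, seed=int(gs), validate=False)
        res = bootstrap_divergence(
            table,
            contrast,
            criterion=criterion,
            boot=BootstrapConfig(n_boot=n_boot, seed=int(gs) + 1),
            subset=subset,
        )
        rows.append(
            {
                "experiment": i,
                "true_onset_ms": config.true_onset_ms,
                "onset_ms": res.onset_ms,
                "mean_divergence_ms": res.mean_divergence_ms,
                "ci_low_ms": res.ci_low_ms,
                "ci_high_ms": res.ci_high_ms,
                "detection_rate": res.detection_rate,
            }
        )
    return pd.DataFrame(rows)
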