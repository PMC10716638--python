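"""Synthetic visual-world experiments with a known divergence point.

The generator reproduces the study design — 32 participants (half male),
four counterbalanced lists, 28 gendered items crossing speaker gender with
referent stereotype at 7 trials per cell plus 28 neutral items, sentence
timings drawn around the published stimulus statistics — and emits verb-
locked binned fixation indicators from a Markov gaze process.

Gaze model. Within a trial the eye occupies one of five states per 50 ms
bin: the two targets, the two distractors, or "none" (off-object / blink).
With probability ``stay_prob`` the state persists into the next bin,
otherwise it refreshes from a mixture in which "none" has probability
``p_offscreen`` and the on-object mass splits between the target pair and
the distractor pair. Before ``true_onset_ms`` (relative to verb onset) the
target share is 0.5; from that bin it moves to ``asymptote_pref`` (abruptly
by default, or linearly over ``ramp_duration_ms``). Within the target pair
the participant-compatible target receives share 0.5 + ``egocentric_effect``.
Because the refresh mixture is the chain's stationary distribution, long-run
state occupancy equals the mixture exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BIN_MS,
    BINNED_COLUMNS,
    WINDOW_MS,
    FixationEvent,
    InterestArea,
    TrialRecord,
    ValidationError,
    bin_grid,
    validate_binned_table,
    write_binned_table,
    write_design,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "build_design",
    "simulate_gaze",
    "simulate_experiment",
    "events_from_binned",
]

# Published per-speaker stimulus timing statistics: mean (sd), ms.
_TIMING = {
    "male": {"duration": (3405, 346), "verb_onset": (1621, 414),
             "verb_offset": (1981, 386), "target_onset": (2742, 376)},
    "female": {"duration": (3352, 339), "verb_onset": (1532, 357),
               "verb_offset": (1907, 345), "target_onset": (2696, 350)},
}

# 300x300 px pictures in the corners of a 1024x768 display.
_CORNERS = ((212.0, 234.0), (812.0, 234.0), (212.0, 534.0), (812.0, 534.0))

_GENDERED_CELLS = (
    ("male", "masculine"),
    ("male", "feminine"),
    ("female", "feminine"),
    ("female", "masculine"),
)


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic experiment.

    Defaults reproduce the study conditions: 32 participants (half male) over
    4 lists, 28 gendered + 28 neutral items, 50 ms bins spanning -1000 to
    +1500 ms around verb onset. ``true_onset_ms`` is the first bin (relative
    to verb onset) at which the refresh mixture's target share departs from
    0.5; with the default ``ramp_duration_ms = 0`` it jumps straight to
    ``asymptote_pref``. ``egocentric_effect = 0`` is the observed null: both
    targets are equally attractive.
    """

    n_participants: int = 32
    n_lists: int = 4
    n_gendered: int = 28
    n_neutral: int = 28
    window: tuple[int, int] = WINDOW_MS
    bin_ms: int = BIN_MS
    true_onset_ms: int = 500
    ramp_duration_ms: int = 0
    asymptote_pref: float = 0.75
    baseline_pref: float = 0.5
    stay_prob: float = 0.85
    p_offscreen: float = 0.2
    egocentric_effect: float = 0.0
    comprehension_error_rate: float = 0.01
    seed: int | None = None

    def validate(self) -> None:
        if self.n_participants % self.n_lists:
            raise ValidationError(
                f"n_participants ({self.n_participants}) must be divisible by "
                f"n_lists ({self.n_lists})"
            )
        if self.n_participants % 2:
            raise ValidationError("n_participants must be even (half male, half female)")
        for name in ("asymptote_pref", "baseline_pref", "stay_prob", "p_offscreen",
                     "comprehension_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.asymptote_pref < 0.5:
            raise ValidationError("asymptote_pref must be >= 0.5")
        if not 0.0 <= 0.5 + self.egocentric_effect <= 1.0:
            raise ValidationError("egocentric_effect must keep shares in [0, 1]")
        if self.true_onset_ms % self.bin_ms:
            raise ValidationError("true_onset_ms must lie on the bin lattice")
        bin_grid(self.window, self.bin_ms)  # raises if off-lattice


@dataclass
class GroundTruth:
    """True divergence bins implied by a :class:`SimulationConfig`."""

    targets_vs_distractors_onset_ms: int | None
    compatible_vs_incompatible_onset_ms: int | None
    config: SimulationConfig

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "GroundTruth":
        return cls(
            targets_vs_distractors_onset_ms=(
                config.true_onset_ms if config.asymptote_pref > 0.5 else None
            ),
            compatible_vs_incompatible_onset_ms=(
                config.true_onset_ms if config.egocentric_effect > 0 else None
            ),
            config=config,
        )

    def to_dict(self) -> dict:
        return {
            "targets_vs_distractors_onset_ms": self.targets_vs_distractors_onset_ms,
            "compatible_vs_incompatible_onset_ms": self.compatible_vs_incompatible_onset_ms,
            "config": dataclasses.asdict(self.config),
        }


def _draw_timings(rng: np.random.Generator, speaker: str) -> tuple[int, int, int, int]:
    """Ordered (verb_onset, verb_offset, target_onset, duration) draws.

    Verb onset follows the published per-speaker normal (clipped so the
    -1000 ms pre-window stays inside the trial); the later landmarks are
    built from positive gap draws whose means match the published column
    means, which guarantees the ordering invariant by construction.
    """
    t = _TIMING[speaker]
    onset = max(1000, int(round(rng.normal(*t["verb_onset"]))))
    gap_off = max(50, int(round(rng.normal(
        t["verb_offset"][0] - t["verb_onset"][0], 80))))
    gap_tgt = max(50, int(round(rng.normal(
        t["target_onset"][0] - t["verb_offset"][0], 100))))
    gap_end = max(300, int(round(rng.normal(
        t["duration"][0] - t["target_onset"][0], 120))))
    offset = onset + gap_off
    target = offset + gap_tgt
    return onset, offset, target, target + gap_end


def _interest_areas(item: str, item_type: str, rng: np.random.Generator) -> tuple[InterestArea, ...]:
    corners = [_CORNERS[i] for i in rng.permutation(4)]
    if item_type == "gendered":
        cells = [("target", "masculine"), ("target", "feminine"),
                 ("distractor", "masculine"), ("distractor", "feminine")]
        labels = [f"{item}_{r[0]}{s[0]}" for r, s in cells]
    else:
        cells = [("target", "neutral"), ("target", "neutral"),
                 ("distractor", "neutral"), ("distractor", "neutral")]
        labels = [f"{item}_t1", f"{item}_t2", f"{item}_d1", f"{item}_d2"]
    return tuple(
        InterestArea(lab, role, st, cx, cy)
        for lab, (role, st), (cx, cy) in zip(labels, cells, corners)
    )


def build_design(config: SimulationConfig, seed: int | None = None) -> list[TrialRecord]:
    """Generate the trial list for every participant.

    Each participant hears every item once; the four lists rotate gendered
    items through the speaker-gender x referent-stereotype cells in a Latin
    square, so each participant gets exactly ``n_gendered / 4`` trials per
    cell and a half/half speaker split on neutral items.
    """
    config.validate()
    if config.n_gendered % 4:
        raise ValidationError("n_gendered must be divisible by 4 (one per cell rotation)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials: list[TrialRecord] = []
    half = config.n_participants // 2
    for i in range(config.n_participants):
        pid = f"p{i + 1:02d}"
        pgender = "male" if i < half else "female"
        list_id = i % config.n_lists + 1
        for j in range(config.n_gendered):
            speaker, referent = _GENDERED_CELLS[(j + list_id) % 4]
            onset, offset, target, duration = _draw_timings(rng, speaker)
            item = f"g{j + 1:02d}"
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    participant_gender=pgender,
                    list_id=list_id,
                    item_id=item,
                    item_type="gendered",
                    speaker_gender=speaker,
                    referent_stereotype=referent,
                    verb_onset_ms=onset,
                    verb_offset_ms=offset,
                    target_onset_ms=target,
                    sentence_duration_ms=duration,
                    interest_areas=_interest_areas(item, "gendered", rng),
                    comprehension_correct=bool(
                        rng.random() >= config.comprehension_error_rate
                    ),
                )
            )
        for j in range(config.n_neutral):
            speaker = "male" if (j + list_id) % 2 == 0 else "female"
            onset, offset, target, duration = _draw_timings(rng, speaker)
            item = f"n{j + 1:02d}"
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    participant_gender=pgender,
                    list_id=list_id,
                    item_id=item,
                    item_type="neutral",
                    speaker_gender=speaker,
                    referent_stereotype="n/a",
                    verb_onset_ms=onset,
                    verb_offset_ms=offset,
                    target_onset_ms=target,
                    sentence_duration_ms=duration,
                    interest_areas=_interest_areas(item, "neutral", rng),
                    comprehension_correct=bool(
                        rng.random() >= config.comprehension_error_rate
                    ),
                )
            )
    return trials


def _target_share(config: SimulationConfig, grid: np.ndarray) -> np.ndarray:
    """Refresh-mixture target share per bin (relative to verb onset)."""
    share = np.full(len(grid), config.baseline_pref, dtype=float)
    delta = config.asymptote_pref - config.baseline_pref
    past = grid >= config.true_onset_ms
    if config.ramp_duration_ms <= 0:
        share[past] = config.asymptote_pref
    else:
        frac = (grid[past] - config.true_onset_ms + config.bin_ms) / config.ramp_duration_ms
        share[past] = config.baseline_pref + delta * np.minimum(1.0, frac)
    return share


def _markov_states(
    rng: np.random.Generator, mixtures: np.ndarray, stay_prob: float
) -> np.ndarray:
    """Sample state paths for many trials at once.

    ``mixtures`` has shape (n_trials, n_bins, n_states): the refresh
    distribution per trial and bin. The first bin draws from its mixture;
    each later bin keeps the previous state with probability ``stay_prob``
    and refreshes otherwise. Returns an (n_trials, n_bins) int array.
    """
    n_trials, n_bins, n_states = mixtures.shape
    states = np.empty((n_trials, n_bins), dtype=np.int64)
    cum = np.cumsum(mixtures, axis=2)
    u = rng.random((n_trials, n_bins))
    keep = rng.random((n_trials, n_bins)) < stay_prob
    states[:, 0] = (u[:, 0, None] > cum[:, 0, :]).sum(axis=1)
    for b in range(1, n_bins):
        fresh = (u[:, b, None] > cum[:, b, :]).sum(axis=1)
        states[:, b] = np.where(keep[:, b], states[:, b - 1], fresh)
    return states


# state order: compatible target, incompatible target, distractor 1,
# distractor 2, none. For neutral trials "compatible" is an arbitrary but
# fixed target (t1), keeping the pair split at exactly 0.5.
_N_STATES = 5


def simulate_gaze(
    design: Sequence[TrialRecord],
    config: SimulationConfig,
    seed: int | None = None,
    validate: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a binned fixation table for a generated design.

    Returns the long-format table plus the ground truth implied by the
    configuration. ``validate=False`` skips the invariant re-check (the
    emitted table satisfies the invariants by construction); useful inside
    large simulation loops.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = bin_grid(config.window, config.bin_ms)
    n_bins = len(grid)
    share = _target_share(config, grid)

    n_trials = len(design)
    # per-state refresh probabilities, identical across trials except that
    # "compatible" is resolved per trial when mapping states to objects
    on = 1.0 - config.p_offscreen
    mix = np.empty((n_bins, _N_STATES), dtype=float)
    mix[:, 0] = on * share * (0.5 + config.egocentric_effect)
    mix[:, 1] = on * share * (0.5 - config.egocentric_effect)
    mix[:, 2] = on * (1.0 - share) * 0.5
    mix[:, 3] = on * (1.0 - share) * 0.5
    mix[:, 4] = config.p_offscreen
    mixtures = np.broadcast_to(mix, (n_trials, n_bins, _N_STATES))
    states = _markov_states(rng, mixtures, config.stay_prob)

    # map states to object labels per trial
    label_matrix = np.empty((n_trials, 4), dtype=object)
    meta_rows = []
    for ti, t in enumerate(design):
        roles = {}
        for ia in t.interest_areas:
            roles.setdefault((ia.role, ia.stereotype), []).append(ia.label)
        if t.item_type == "gendered":
            comp = "masculine" if t.participant_gender == "male" else "feminine"
            incomp = "feminine" if comp == "masculine" else "masculine"
            ordered = [
                roles[("target", comp)][0],
                roles[("target", incomp)][0],
                roles[("distractor", "masculine")][0],
                roles[("distractor", "feminine")][0],
            ]
        else:
            tgts = sorted(roles[("target", "neutral")])
            dsts = sorted(roles[("distractor", "neutral")])
            ordered = [tgts[0], tgts[1], dsts[0], dsts[1]]
        label_matrix[ti] = ordered
        meta_rows.append(
            (t.participant_id, t.participant_gender, t.item_id, t.item_type,
             t.speaker_gender, t.referent_stereotype)
        )

    # expand to the long format: 4 object rows (label-sorted) per (trial, bin)
    role_of = {ia.label: (ia.role, ia.stereotype) for t in design for ia in t.interest_areas}
    labels_sorted = np.sort(label_matrix, axis=1)
    # rank[ti, s]: position of state s's label within the sorted labels
    rank = np.argsort(np.argsort(label_matrix, axis=1), axis=1)
    roles_sorted = np.empty((n_trials, 4), dtype=object)
    stereo_sorted = np.empty((n_trials, 4), dtype=object)
    for ti in range(n_trials):
        for k in range(4):
            roles_sorted[ti, k], stereo_sorted[ti, k] = role_of[labels_sorted[ti, k]]

    n_cells = n_trials * n_bins
    trial_idx = np.repeat(np.arange(n_trials), n_bins * 4)
    bin_col = np.tile(np.repeat(grid, 4), n_trials)
    slot = np.tile(np.arange(4), n_cells)

    # fixated: state s in 0..3 marks label_matrix[trial, s]; 4 marks none
    fixated = np.zeros(n_trials * n_bins * 4, dtype=np.int64)
    st_flat = states.reshape(-1)  # (n_trials * n_bins,)
    cell_trial = np.repeat(np.arange(n_trials), n_bins)
    on_mask = st_flat < 4
    on_cells = np.flatnonzero(on_mask)
    pos = rank[cell_trial[on_mask], st_flat[on_mask]]
    fixated[on_cells * 4 + pos] = 1

    meta = np.asarray(meta_rows, dtype=object)
    table = pd.DataFrame(
        {
            "participant": meta[trial_idx, 0],
            "participant_gender": meta[trial_idx, 1],
            "trial": meta[trial_idx, 2],
            "item_type": meta[trial_idx, 3],
            "speaker_gender": meta[trial_idx, 4],
            "referent_stereotype": meta[trial_idx, 5],
            "bin": bin_col,
            "object": labels_sorted[trial_idx, slot],
            "role": roles_sorted[trial_idx, slot],
            "stereotype": stereo_sorted[trial_idx, slot],
            "fixated": fixated,
        },
        columns=BINNED_COLUMNS,
    )
    if validate:
        table = validate_binned_table(table, config.window, config.bin_ms)
    return table, GroundTruth.from_config(config)


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Generate a full experiment and write design, binned table, and ground
    truth to ``out_dir``. Byte-identical outputs for identical (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed if seed is None else seed)
    design_seed, gaze_seed = (int(s) for s in root.integers(0, 2**31 - 1, size=2))
    design = build_design(config, seed=design_seed)
    table, truth = simulate_gaze(design, config, seed=gaze_seed)
    paths = {
        "design": out / "design.csv",
        "binned": out / "binned_fixations.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_design(design, paths["design"])
    write_binned_table(table, paths["binned"])
    truth_dict = truth.to_dict()
    truth_dict["config"]["seed"] = config.seed if seed is None else seed
    paths["ground_truth"].write_text(json.dumps(truth_dict, indent=2, sort_keys=True))
    return paths


def events_from_binned(
    table: pd.DataFrame, design: Sequence[TrialRecord]
) -> list[FixationEvent]:
    """Thin adapter emitting coordinate-level fixation events from a binned
    table, for exercising the report reader and binner.

    Consecutive bins fixating the same object become one event centred in
    that object's interest area; empty bins leave gaps. Binning the result
    with the same design reproduces the input table.
    """
    by_trial = {(t.participant_id, t.item_id): t for t in design}
    events: list[FixationEvent] = []
    fixed = table[table["fixated"] == 1].sort_values(["participant", "trial", "bin"])
    for (pid, trial_id), grp in fixed.groupby(["participant", "trial"], sort=True):
        t = by_trial[(pid, trial_id)]
        centers = {ia.label: (ia.center_x, ia.center_y) for ia in t.interest_areas}
        run_start = run_end = None
        run_obj = None
        for b, obj in zip(grp["bin"], grp["object"]):
            abs_start = t.verb_onset_ms + int(b)
            if run_obj == obj and abs_start == run_end:
                run_end += BIN_MS
            else:
                if run_obj is not None:
                    x, y = centers[run_obj]
                    events.append(FixationEvent(pid, trial_id, run_start, run_end, x, y))
                run_obj, run_start, run_end = obj, abs_start, abs_start + BIN_MS
        if run_obj is not None:
            x, y = centers[run_obj]
            events.append(FixationEvent(pid, trial_id, run_start, run_end, x, y))
    events.sort(key=lambda e: (e.participant_id, e.trial_id, e.start_ms))
    return events
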