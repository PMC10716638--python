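"""Verb-locked binomial binning and fixation-proportion curves.

Fixations are time-locked to verb onset and coded binomially per object and
50 ms bin: an object scores 1 in a bin iff gaze lay inside its interest area
for a strict majority of the bin. Blinks and out-of-area gaze score 0 for
every object but the bin stays in the data. Proportion curves then express,
per participant and bin, the share of looks to one object set out of the
looks to the union of two sets, so that 0.50 is the exact no-preference
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    BIN_MS,
    BINNED_COLUMNS,
    WINDOW_MS,
    FixationEvent,
    TrialRecord,
    ValidationError,
    bin_grid,
    validate_binned_table,
)

__all__ = [
    "RoleInfo",
    "ContrastSpec",
    "ProportionCurves",
    "CONTRASTS",
    "SUBSETS",
    "bin_fixations",
    "assign_roles",
    "select_trials",
    "proportion_curves",
    "comprehension_accuracy",
]


@dataclass(frozen=True)
class RoleInfo:
    """Analysis role of one displayed object for one trial/participant."""

    role: str
    stereotype: str
    participant_compatible: bool | None
    speaker_compatible: bool | None


def assign_roles(trial: TrialRecord, participant_gender: str | None = None) -> dict[str, RoleInfo]:
    """Map each object label to its role, stereotype and compatibility flags.

    An object is *participant compatible* iff its stereotype matches the
    participant's gender (masculine <-> male, feminine <-> female), and
    *speaker compatible* iff it matches the speaker's gender. On neutral
    trials both flags are ``None``.
    """
    pg = participant_gender or trial.participant_gender
    mapping: dict[str, RoleInfo] = {}
    for ia in trial.interest_areas:
        if trial.item_type == "gendered":
            pc = (ia.stereotype == "masculine") == (pg == "male")
            sc = (ia.stereotype == "masculine") == (trial.speaker_gender == "male")
        else:
            pc = sc = None
        mapping[ia.label] = RoleInfo(ia.role, ia.stereotype, pc, sc)
    return mapping


def _locate(ia_list, x: float, y: float) -> str | None:
    for ia in ia_list:
        if ia.contains(x, y):
            return ia.label
    return None


def bin_fixations(
    events: Iterable[FixationEvent],
    trials: Sequence[TrialRecord],
    window: tuple[int, int] = WINDOW_MS,
    bin_ms: int = BIN_MS,
) -> pd.DataFrame:
    """Code fixation events binomially per 50 ms bin and object.

    Bins are identified by their left edge relative to verb onset; an object
    is coded 1 in a bin iff non-blink gaze inside its interest area covers a
    strict majority (> bin_ms/2) of that bin. Blinks and gaze outside every
    interest area contribute nothing, so a fully blinked trial yields all-zero
    rows. Events referencing a trial absent from the design raise a keyed
    error listing the orphans.
    """
    grid = bin_grid(window, bin_ms)
    by_trial: dict[tuple[str, str], TrialRecord] = {
        (t.participant_id, t.item_id): t for t in trials
    }
    ev_groups: dict[tuple[str, str], list[FixationEvent]] = {}
    for e in events:
        ev_groups.setdefault((e.participant_id, e.trial_id), []).append(e)
    orphans = sorted(k for k in ev_groups if k not in by_trial)
    if orphans:
        raise ValidationError(
            f"events reference trials absent from the design: {orphans[:10]}"
        )

    rows: list[tuple] = []
    for key, trial in by_trial.items():
        labels = [ia.label for ia in trial.interest_areas]
        meta = {ia.label: ia for ia in trial.interest_areas}
        # per-object occupancy (ms) in each bin of this trial
        occupancy = {lab: np.zeros(len(grid), dtype=np.int64) for lab in labels}
        for e in ev_groups.get(key, ()):
            if e.is_blink:
                continue
            lab = _locate(trial.interest_areas, e.x, e.y)
            if lab is None:
                continue
            # overlap of [start, end) with each bin, in trial time
            starts = grid + trial.verb_onset_ms
            lo = np.maximum(e.start_ms, starts)
            hi = np.minimum(e.end_ms, starts + bin_ms)
            occupancy[lab] += np.maximum(0, hi - lo)
        for b_idx, b in enumerate(grid):
            for lab in labels:
                fix = int(occupancy[lab][b_idx] * 2 > bin_ms)  # strict majority
                rows.append(
                    (
                        trial.participant_id,
                        trial.participant_gender,
                        trial.item_id,
                        trial.item_type,
                        trial.speaker_gender,
                        trial.referent_stereotype,
                        int(b),
                        lab,
                        meta[lab].role,
                        meta[lab].stereotype,
                        fix,
                    )
                )
    table = pd.DataFrame(rows, columns=BINNED_COLUMNS)
    return validate_binned_table(table, window, bin_ms)


# ---------------------------------------------------------------------------
# trial subsets and contrasts
# ---------------------------------------------------------------------------

def _subset_mask(table: pd.DataFrame, subset: str) -> pd.Series:
    if subset == "all_gendered":
        return table["item_type"] == "gendered"
    if subset == "gender_match":
        return (table["item_type"] == "gendered") & (
            table["participant_gender"] == table["speaker_gender"]
        )
    if subset == "gender_mismatch":
        return (table["item_type"] == "gendered") & (
            table["participant_gender"] != table["speaker_gender"]
        )
    if subset == "neutral":
        return table["item_type"] == "neutral"
    raise ValidationError(
        f"unknown subset {subset!r}; expected one of {sorted(SUBSETS)}"
    )


SUBSETS = ("all_gendered", "gender_match", "gender_mismatch", "neutral")


def select_trials(table: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Restrict a binned table to one trial subset.

    ``gender_match`` keeps trials where participant and speaker genders agree;
    ``gender_mismatch`` those where they differ; together they partition
    ``all_gendered``. An empty selection is an error.
    """
    out = table[_subset_mask(table, subset)]
    if len(out) == 0:
        raise ValidationError(f"subset {subset!r} selects no trials")
    return out


def _participant_compatible(table: pd.DataFrame) -> pd.Series:
    return (table["stereotype"] == "masculine") == (table["participant_gender"] == "male")


@dataclass(frozen=True)
class ContrastSpec:
    """A named A-vs-B fixation contrast.

    ``set_a`` and ``set_b`` are vectorised predicates over the annotated
    binned table selecting the two disjoint object sets; ``default_subset``
    names the trial subset the contrast is normally run on.
    """

    name: str
    set_a: Callable[[pd.DataFrame], pd.Series]
    set_b: Callable[[pd.DataFrame], pd.Series]
    default_subset: str = "all_gendered"
    valid_subsets: tuple[str, ...] = SUBSETS


CONTRASTS: dict[str, ContrastSpec] = {
    # both targets vs both distractors: associative prediction
    "targets_vs_distractors": ContrastSpec(
        name="targets_vs_distractors",
        set_a=lambda t: t["role"] == "target",
        set_b=lambda t: t["role"] == "distractor",
    ),
    # own-gender-compatible target vs the other target: egocentric prediction
    "compatible_vs_incompatible": ContrastSpec(
        name="compatible_vs_incompatible",
        set_a=lambda t: (t["role"] == "target") & _participant_compatible(t),
        set_b=lambda t: (t["role"] == "target") & ~_participant_compatible(t),
        valid_subsets=("all_gendered", "gender_match", "gender_mismatch"),
    ),
}


@dataclass
class ProportionCurves:
    """Per-participant and grand-average fixation-proportion time courses.

    ``by_participant`` holds one row per (participant, bin) with the
    proportion ``p_a`` of looks to set A out of looks to A or B and the
    denominator ``n_informative``; ``p_a`` is NaN where the denominator is 0.
    ``summary`` holds the per-bin grand mean, standard error (sd/sqrt(n))
    and number of participants with a defined value.
    """

    contrast: str
    subset: str
    by_participant: pd.DataFrame
    summary: pd.DataFrame
    n_trials: dict[str, int] = field(default_factory=dict)


def proportion_curves(
    table: pd.DataFrame,
    contrast: ContrastSpec | str,
    subset: str | None = None,
    denominator: str = "pair",
) -> ProportionCurves:
    """Build A-vs-(A u B) proportion curves for one contrast.

    denominator="pair" divides looks-to-A by looks-to-A-or-B (0.50 is the
    exact null); denominator="trial" divides by the number of selected
    trials, so bins where gaze was elsewhere drag both curves down.
    """
    spec = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    subset = subset or spec.default_subset
    if subset not in spec.valid_subsets:
        raise ValidationError(
            f"contrast {spec.name!r} is not defined on subset {subset!r}"
        )
    sel = select_trials(table, subset)

    in_a = spec.set_a(sel)
    in_b = spec.set_b(sel)
    if (in_a & in_b).any():
        raise ValidationError(f"contrast {spec.name!r}: sets A and B overlap")
    fx = sel["fixated"].to_numpy()
    work = pd.DataFrame(
        {
            "participant": sel["participant"].to_numpy(),
            "trial": sel["trial"].to_numpy(),
            "bin": sel["bin"].to_numpy(),
            "a": fx * in_a.to_numpy(),
            "b": fx * in_b.to_numpy(),
        }
    )
    per = work.groupby(["participant", "bin"], sort=True).agg(
        a=("a", "sum"), b=("b", "sum"), n_trials=("trial", "nunique")
    )
    if denominator == "pair":
        denom = (per["a"] + per["b"]).to_numpy().astype(float)
    elif denominator == "trial":
        denom = per["n_trials"].to_numpy().astype(float)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(denom > 0, per["a"].to_numpy() / np.where(denom > 0, denom, 1), np.nan)
    by_participant = per.reset_index()[["participant", "bin"]].assign(
        p_a=p_a, n_informative=(per["a"] + per["b"]).to_numpy()
    )

    g = by_participant.groupby("bin")["p_a"]
    n = g.count()
    mean = g.mean()
    sd = g.std(ddof=1)
    summary = pd.DataFrame(
        {
            "bin": n.index.to_numpy(),
            "mean": mean.to_numpy(),
            "se": (sd / np.sqrt(n)).to_numpy(),
            "n": n.to_numpy(),
        }
    ).reset_index(drop=True)
    n_trials = (
        sel.groupby("participant", observed=True)["trial"].nunique().to_dict()
    )
    return ProportionCurves(
        contrast=spec.name,
        subset=subset,
        by_participant=by_participant,
        summary=summary,
        n_trials=n_trials,
    )


def comprehension_accuracy(
    trials: Sequence[TrialRecord],
) -> tuple[float, pd.Series]:
    """Overall and per-participant proportion of correct comprehension answers."""
    if not trials:
        raise ValidationError("no trials supplied")
    df = pd.DataFrame(
        {
            "participant": [t.participant_id for t in trials],
            "correct": [t.comprehension_correct for t in trials],
        }
    )
    per = df.groupby("participant")["correct"].mean()
    return float(df["correct"].mean()), per
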