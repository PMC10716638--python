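"""Domain types and delimited-text readers/writers.

The on-disk dialect is comma-delimited UTF-8 with a header row. Times are
integer milliseconds; a 50 ms bin is identified by its left edge and covers
the half-open interval [start, start + 50). Screen coordinates follow the
usual eye-tracker convention: origin at the top-left, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "InterestArea",
    "FixationEvent",
    "TrialRecord",
    "BIN_MS",
    "WINDOW_MS",
    "bin_grid",
    "BINNED_COLUMNS",
    "read_fixation_report",
    "write_fixation_report",
    "read_design",
    "write_design",
    "read_binned_table",
    "write_binned_table",
    "validate_binned_table",
]


class FormatError(ValueError):
    """A file does not have the expected columns or dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: Bin width used throughout the analysis, in ms.
BIN_MS = 50

#: Analysis window around verb onset, in ms (left-closed, right-open).
WINDOW_MS = (-1000, 1500)


def bin_grid(window: tuple[int, int] = WINDOW_MS, bin_ms: int = BIN_MS) -> np.ndarray:
    """Left edges of the 50 ms bins spanning ``window`` (relative to verb onset)."""
    lo, hi = window
    if lo % bin_ms or hi % bin_ms or hi <= lo:
        raise ValidationError(f"window {window} is not on the {bin_ms} ms lattice")
    return np.arange(lo, hi, bin_ms)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

ROLES = ("target", "distractor")
STEREOTYPES = ("masculine", "feminine", "neutral")
GENDERS = ("male", "female")
ITEM_TYPES = ("gendered", "neutral")


@dataclass(frozen=True)
class InterestArea:
    """A screen region within which a fixation counts as a look to one object.

    The experiment draws each picture inside a 300 x 300 px square; a gaze
    sample belongs to the area if it falls within the (inclusive) square
    around ``(center_x, center_y)``.
    """

    label: str
    role: str
    stereotype: str
    center_x: float
    center_y: float
    width: float = 300.0
    height: float = 300.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"interest area {self.label!r}: bad role {self.role!r}")
        if self.stereotype not in STEREOTYPES:
            raise ValidationError(
                f"interest area {self.label!r}: bad stereotype {self.stereotype!r}"
            )
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"interest area {self.label!r}: non-positive size")

    def contains(self, x: float, y: float) -> bool:
        return (
            abs(x - self.center_x) <= self.width / 2
            and abs(y - self.center_y) <= self.height / 2
        )


@dataclass(frozen=True)
class FixationEvent:
    """One fixation (or blink) of a participant within a trial.

    Times are trial time in ms from sentence-recording start; blinks carry no
    usable coordinates and are coded as looks to no object downstream.
    """

    participant_id: str
    trial_id: str
    start_ms: int
    end_ms: int
    x: float
    y: float
    is_blink: bool = False

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValidationError(
                f"fixation {self.participant_id}/{self.trial_id}: "
                f"end ({self.end_ms}) must exceed start ({self.start_ms})"
            )


@dataclass
class TrialRecord:
    """Design metadata for a single trial.

    A gendered trial shows four objects crossing role (target/distractor)
    with stereotype (masculine/feminine); a neutral trial shows two neutral
    targets and two neutral distractors. ``referent_stereotype`` is the
    stereotype of the object the speaker actually named ("n/a" on neutral
    trials).
    """

    participant_id: str
    participant_gender: str
    list_id: int
    item_id: str
    item_type: str
    speaker_gender: str
    referent_stereotype: str
    verb_onset_ms: int
    verb_offset_ms: int
    target_onset_ms: int
    sentence_duration_ms: int
    interest_areas: tuple[InterestArea, ...]
    comprehension_correct: bool

    def __post_init__(self) -> None:
        if self.participant_gender not in GENDERS:
            raise ValidationError(f"trial {self.item_id}: bad participant_gender")
        if self.speaker_gender not in GENDERS:
            raise ValidationError(f"trial {self.item_id}: bad speaker_gender")
        if self.item_type not in ITEM_TYPES:
            raise ValidationError(f"trial {self.item_id}: bad item_type")
        if not 1 <= int(self.list_id) <= 4:
            raise ValidationError(f"trial {self.item_id}: list_id must be 1-4")
        if not (
            self.verb_onset_ms
            < self.verb_offset_ms
            < self.target_onset_ms
            < self.sentence_duration_ms
        ):
            raise ValidationError(
                f"trial {self.participant_id}/{self.item_id}: timings must satisfy "
                "verb_onset < verb_offset < target_onset < duration "
                f"(got {self.verb_onset_ms}, {self.verb_offset_ms}, "
                f"{self.target_onset_ms}, {self.sentence_duration_ms})"
            )
        self.interest_areas = tuple(self.interest_areas)
        if len(self.interest_areas) != 4:
            raise ValidationError(
                f"trial {self.participant_id}/{self.item_id}: "
                f"expected 4 interest areas, got {len(self.interest_areas)}"
            )
        cells = sorted((ia.role, ia.stereotype) for ia in self.interest_areas)
        if self.item_type == "gendered":
            if self.referent_stereotype not in ("masculine", "feminine"):
                raise ValidationError(
                    f"trial {self.participant_id}/{self.item_id}: gendered trial "
                    f"needs a masculine/feminine referent, got "
                    f"{self.referent_stereotype!r}"
                )
            expected = sorted(
                (r, s) for r in ROLES for s in ("masculine", "feminine")
            )
            if cells != expected:
                raise ValidationError(
                    f"trial {self.participant_id}/{self.item_id}: gendered trial must "
                    "show exactly one object per role x stereotype cell"
                )
        else:
            if self.referent_stereotype != "n/a":
                raise ValidationError(
                    f"trial {self.participant_id}/{self.item_id}: neutral trial must "
                    "have referent_stereotype 'n/a'"
                )
            if cells != [("distractor", "neutral")] * 2 + [("target", "neutral")] * 2:
                raise ValidationError(
                    f"trial {self.participant_id}/{self.item_id}: neutral trial must "
                    "show two neutral targets and two neutral distractors"
                )


# ---------------------------------------------------------------------------
# fixation reports
# ---------------------------------------------------------------------------

_FIXREP_COLUMNS = ["participant", "trial", "start", "end", "x", "y", "blink"]


def read_fixation_report(path: str | Path) -> list[FixationEvent]:
    """Read a delimited fixation report into a list of :class:`FixationEvent`.

    Required columns: participant, trial, start, end, x, y, blink. Events are
    returned ordered by (participant, trial, start). A missing column raises
    :class:`FormatError`; a non-numeric or inverted time raises
    :class:`ValidationError` naming the offending line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FIXREP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    events: list[FixationEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
            blink = bool(int(row.blink))
            x = float("nan") if blink else float(row.x)
            y = float("nan") if blink else float(row.y)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{line_no}: non-numeric field ({exc})") from exc
        try:
            events.append(
                FixationEvent(str(row.participant), str(row.trial), start, end, x, y, blink)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    events.sort(key=lambda e: (e.participant_id, e.trial_id, e.start_ms))
    return events


def write_fixation_report(events: Iterable[FixationEvent], path: str | Path) -> None:
    rows = [
        {
            "participant": e.participant_id,
            "trial": e.trial_id,
            "start": e.start_ms,
            "end": e.end_ms,
            "x": "" if e.is_blink else e.x,
            "y": "" if e.is_blink else e.y,
            "blink": int(e.is_blink),
        }
        for e in sorted(events, key=lambda e: (e.participant_id, e.trial_id, e.start_ms))
    ]
    pd.DataFrame(rows, columns=_FIXREP_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design tables
# ---------------------------------------------------------------------------

_DESIGN_SCALARS = [
    "participant",
    "participant_gender",
    "list_id",
    "item",
    "item_type",
    "speaker_gender",
    "referent_stereotype",
    "verb_onset_ms",
    "verb_offset_ms",
    "target_onset_ms",
    "sentence_duration_ms",
    "comprehension_correct",
]
_IA_FIELDS = ["label", "role", "stereotype", "center_x", "center_y", "width", "height"]
_DESIGN_COLUMNS = _DESIGN_SCALARS + [
    f"ia{k}_{f}" for k in range(1, 5) for f in _IA_FIELDS
]


def write_design(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write one row per trial; the four interest areas are flattened as
    labelled column groups ``ia1_* .. ia4_*``."""
    rows = []
    for t in trials:
        row: dict[str, object] = {
            "participant": t.participant_id,
            "participant_gender": t.participant_gender,
            "list_id": t.list_id,
            "item": t.item_id,
            "item_type": t.item_type,
            "speaker_gender": t.speaker_gender,
            "referent_stereotype": t.referent_stereotype,
            "verb_onset_ms": t.verb_onset_ms,
            "verb_offset_ms": t.verb_offset_ms,
            "target_onset_ms": t.target_onset_ms,
            "sentence_duration_ms": t.sentence_duration_ms,
            "comprehension_correct": int(t.comprehension_correct),
        }
        for k, ia in enumerate(t.interest_areas, start=1):
            for f in _IA_FIELDS:
                row[f"ia{k}_{f}"] = getattr(ia, f)
        rows.append(row)
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(path, index=False)


def read_design(path: str | Path) -> list[TrialRecord]:
    """Read a design table; every :class:`TrialRecord` invariant is checked."""
    df = pd.read_csv(path, keep_default_na=False)  # "n/a" is a literal level
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing[:6])}")
    trials: list[TrialRecord] = []
    for i, row in df.iterrows():
        ias = tuple(
            InterestArea(
                label=str(row[f"ia{k}_label"]),
                role=str(row[f"ia{k}_role"]),
                stereotype=str(row[f"ia{k}_stereotype"]),
                center_x=float(row[f"ia{k}_center_x"]),
                center_y=float(row[f"ia{k}_center_y"]),
                width=float(row[f"ia{k}_width"]),
                height=float(row[f"ia{k}_height"]),
            )
            for k in range(1, 5)
        )
        try:
            trials.append(
                TrialRecord(
                    participant_id=str(row["participant"]),
                    participant_gender=str(row["participant_gender"]),
                    list_id=int(row["list_id"]),
                    item_id=str(row["item"]),
                    item_type=str(row["item_type"]),
                    speaker_gender=str(row["speaker_gender"]),
                    referent_stereotype=str(row["referent_stereotype"]),
                    verb_onset_ms=int(row["verb_onset_ms"]),
                    verb_offset_ms=int(row["verb_offset_ms"]),
                    target_onset_ms=int(row["target_onset_ms"]),
                    sentence_duration_ms=int(row["sentence_duration_ms"]),
                    interest_areas=ias,
                    comprehension_correct=bool(int(row["comprehension_correct"])),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return trials


# ---------------------------------------------------------------------------
# binned fixation tables
# ---------------------------------------------------------------------------

#: Canonical long-format column order of a binned fixation table. One row per
#: (participant, trial, bin, object); ``bin`` is the bin's left edge in ms
#: relative to verb onset; ``fixated`` is the 0/1 binomial code.
BINNED_COLUMNS = [
    "participant",
    "participant_gender",
    "trial",
    "item_type",
    "speaker_gender",
    "referent_stereotype",
    "bin",
    "object",
    "role",
    "stereotype",
    "fixated",
]


def validate_binned_table(
    table: pd.DataFrame, window: tuple[int, int] = WINDOW_MS, bin_ms: int = BIN_MS
) -> pd.DataFrame:
    """Check every binned-table invariant; return the table sorted canonically.

    Raises :class:`ValidationError` on a missing column, an off-lattice bin,
    duplicate (trial, bin, object) rows, a (trial, bin) cell without exactly
    four object rows, or a bin in which more than one object is coded 1.
    """
    missing = [c for c in BINNED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"binned table missing column(s) {', '.join(missing)}")
    if len(table) == 0:
        return table.loc[:, BINNED_COLUMNS]

    grid = bin_grid(window, bin_ms)
    bins = table["bin"].to_numpy()
    off = ~np.isin(bins, grid)
    if off.any():
        bad = sorted(set(np.asarray(bins)[off].tolist()))[:5]
        raise ValidationError(f"bins off the {window} x {bin_ms} ms lattice: {bad}")
    if not table["fixated"].isin([0, 1]).all():
        raise ValidationError("fixated must be coded 0/1")

    key = ["participant", "trial", "bin"]
    if table.duplicated(subset=key + ["object"]).any():
        dup = table[table.duplicated(subset=key + ["object"], keep=False)]
        raise ValidationError(
            f"duplicate (participant, trial, bin, object) rows, e.g. "
            f"{dup.iloc[0][key + ['object']].tolist()}"
        )
    counts = table.groupby(key, observed=True, sort=False)["object"].size()
    if (counts != 4).any():
        bad_key = counts[counts != 4].index[0]
        raise ValidationError(
            f"every (participant, trial, bin) needs exactly 4 object rows; "
            f"{bad_key} has {counts[counts != 4].iloc[0]}"
        )
    looks = table.groupby(key, observed=True, sort=False)["fixated"].sum()
    if (looks > 1).any():
        bad_key = looks[looks > 1].index[0]
        raise ValidationError(
            f"at most one object may be fixated per (participant, trial, bin); "
            f"violated at {bad_key}"
        )
    return (
        table.loc[:, BINNED_COLUMNS]
        .sort_values(["participant", "trial", "bin", "object"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_binned_table(table: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a binned table with deterministic row order."""
    validate_binned_table(table).to_csv(path, index=False)


def read_binned_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        keep_default_na=False,
        dtype={
            "participant": str,
            "trial": str,
            "object": str,
            "bin": int,
            "fixated": int,
        },
    )
    return validate_binned_table(df)
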