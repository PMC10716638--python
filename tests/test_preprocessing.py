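"""Binomial binning, role mapping, trial subsets, and proportion curves."""

import numpy as np
import pandas as pd
import pytest

from gazedpa.io import (
    BINNED_COLUMNS,
    FixationEvent,
    InterestArea,
    TrialRecord,
    ValidationError,
    bin_grid,
)
from gazedpa.preprocessing import (
    CONTRASTS,
    ContrastSpec,
    assign_roles,
    bin_fixations,
    comprehension_accuracy,
    proportion_curves,
    select_trials,
)
from gazedpa.simulate import events_from_binned


def make_trial(pid="p01", pgender="male", item="g01", speaker="female",
               verb_onset=1600, correct=True):
    return TrialRecord(
        participant_id=pid,
        participant_gender=pgender,
        list_id=1,
        item_id=item,
        item_type="gendered",
        speaker_gender=speaker,
        referent_stereotype="masculine",
        verb_onset_ms=verb_onset,
        verb_offset_ms=verb_onset + 380,
        target_onset_ms=verb_onset + 1120,
        sentence_duration_ms=verb_onset + 1800,
        interest_areas=(
            InterestArea(f"{item}_tm", "target", "masculine", 212, 234),
            InterestArea(f"{item}_tf", "target", "feminine", 812, 234),
            InterestArea(f"{item}_dm", "distractor", "masculine", 212, 534),
            InterestArea(f"{item}_df", "distractor", "feminine", 812, 534),
        ),
        comprehension_correct=correct,
    )


class TestBinFixations:
    def test_centred_fixation_marks_exactly_its_bins(self):
        trial = make_trial()
        # 500 ms on the masculine target, aligned with bins 0..450
        events = [FixationEvent("p01", "g01", 1600, 2100, 212.0, 234.0)]
        table = bin_fixations(events, [trial])
        tm = table[table["object"] == "g01_tm"].set_index("bin")["fixated"]
        assert all(tm.loc[b] == 1 for b in range(0, 500, 50))
        assert tm.sum() == 10
        assert table[table["object"] != "g01_tm"]["fixated"].sum() == 0

    def test_full_trial_blink_codes_all_zero(self):
        trial = make_trial()
        events = [FixationEvent("p01", "g01", 0, 4000, float("nan"), float("nan"), True)]
        table = bin_fixations(events, [trial])
        assert table["fixated"].sum() == 0
        assert len(table) == 50 * 4

    def test_minority_coverage_is_zero(self):
        trial = make_trial()
        # 20 ms of bin 0 -- a minority -- then gaze elsewhere off-area
        events = [FixationEvent("p01", "g01", 1600, 1620, 212.0, 234.0)]
        table = bin_fixations(events, [trial])
        assert table["fixated"].sum() == 0

    def test_exact_half_coverage_ties_to_zero(self):
        trial = make_trial()
        events = [FixationEvent("p01", "g01", 1600, 1625, 212.0, 234.0)]
        table = bin_fixations(events, [trial])
        assert table["fixated"].sum() == 0

    def test_majority_coverage_is_one(self):
        trial = make_trial()
        events = [FixationEvent("p01", "g01", 1600, 1626, 212.0, 234.0)]
        table = bin_fixations(events, [trial])
        assert table["fixated"].sum() == 1

    def test_orphan_trial_raises_keyed_error(self):
        trial = make_trial()
        events = [FixationEvent("p01", "nope", 1600, 1700, 212.0, 234.0)]
        with pytest.raises(ValidationError, match="nope"):
            bin_fixations(events, [trial])

    def test_matches_per_ms_occupancy_brute_force(self):
        """Oracle: count gaze-in-area per millisecond; a bin is 1 iff one
        object covers a strict majority of its 50 ms."""
        rng = np.random.default_rng(42)
        trial = make_trial()
        ias = trial.interest_areas
        # non-overlapping random events walking through the trial
        events, t = [], 400
        while t < 3400:
            dur = int(rng.integers(30, 420))
            if rng.random() < 0.15:
                events.append(FixationEvent("p01", "g01", t, t + dur,
                                            float("nan"), float("nan"), True))
            else:
                if rng.random() < 0.2:
                    x, y = 512.0, 384.0  # screen centre: outside every area
                else:
                    ia = ias[rng.integers(4)]
                    x, y = ia.center_x + 10.0, ia.center_y - 5.0
                events.append(FixationEvent("p01", "g01", t, t + dur, x, y))
            t += dur + int(rng.integers(0, 60))
        table = bin_fixations(events, [trial])

        grid = bin_grid()
        expect = {}
        for b in grid:
            counts = {ia.label: 0 for ia in ias}
            for ms in range(trial.verb_onset_ms + b, trial.verb_onset_ms + b + 50):
                for e in events:
                    if e.start_ms <= ms < e.end_ms and not e.is_blink:
                        for ia in ias:
                            if ia.contains(e.x, e.y):
                                counts[ia.label] += 1
                        break
            for lab, c in counts.items():
                expect[(b, lab)] = int(c > 25)
        got = table.set_index(["bin", "object"])["fixated"].to_dict()
        assert got == expect

    def test_invariant_to_splitting_events(self):
        rng = np.random.default_rng(7)
        trial = make_trial()
        events = [
            FixationEvent("p01", "g01", 700, 1460, 212.0, 234.0),
            FixationEvent("p01", "g01", 1500, 2380, 812.0, 234.0),
            FixationEvent("p01", "g01", 2380, 3100, 212.0, 534.0),
        ]
        split = []
        for e in events:
            mid = int(rng.integers(e.start_ms + 1, e.end_ms))
            split.append(FixationEvent(e.participant_id, e.trial_id, e.start_ms, mid, e.x, e.y))
            split.append(FixationEvent(e.participant_id, e.trial_id, mid, e.end_ms, e.x, e.y))
        pd.testing.assert_frame_equal(
            bin_fixations(events, [trial]), bin_fixations(split, [trial])
        )

    def test_round_trip_through_event_adapter(self, tiny_experiment):
        """Binned table -> coordinate events -> binning reproduces the table."""
        design, table, _ = tiny_experiment
        events = events_from_binned(table, design)
        rebinned = bin_fixations(events, design)
        pd.testing.assert_frame_equal(rebinned, table)


class TestAssignRoles:
    def test_male_participant_compatible_with_masculine_target(self):
        trial = make_trial(pgender="male", speaker="male")
        roles = assign_roles(trial)
        assert roles["g01_tm"].participant_compatible is True
        assert roles["g01_tm"].role == "target"

    def test_female_participant_flips_compatibility(self):
        trial = make_trial(pgender="male", speaker="male")
        roles = assign_roles(trial, participant_gender="female")
        assert roles["g01_tm"].participant_compatible is False
        assert roles["g01_tf"].participant_compatible is True

    def test_speaker_and_participant_flags_are_independent(self):
        trial = make_trial(pgender="female", speaker="male")
        roles = assign_roles(trial)
        assert roles["g01_tm"].speaker_compatible is True
        assert roles["g01_tm"].participant_compatible is False

    def test_neutral_trial_has_na_compatibility(self):
        neutral = TrialRecord(
            participant_id="p01", participant_gender="male", list_id=1,
            item_id="n01", item_type="neutral", speaker_gender="male",
            referent_stereotype="n/a", verb_onset_ms=1600, verb_offset_ms=1980,
            target_onset_ms=2720, sentence_duration_ms=3400,
            interest_areas=(
                InterestArea("n01_t1", "target", "neutral", 212, 234),
                InterestArea("n01_t2", "target", "neutral", 812, 234),
                InterestArea("n01_d1", "distractor", "neutral", 212, 534),
                InterestArea("n01_d2", "distractor", "neutral", 812, 534),
            ),
            comprehension_correct=True,
        )
        roles = assign_roles(neutral)
        assert all(r.participant_compatible is None for r in roles.values())


class TestSelectTrials:
    def test_all_gendered_keeps_28_trials_per_participant(self, default_experiment):
        _, table, _ = default_experiment
        sel = select_trials(table, "all_gendered")
        counts = sel.groupby("participant")["trial"].nunique()
        assert (counts == 28).all()

    def test_match_and_mismatch_partition_gendered(self, default_experiment):
        _, table, _ = default_experiment
        gendered = select_trials(table, "all_gendered")
        match = select_trials(table, "gender_match")
        mismatch = select_trials(table, "gender_mismatch")
        assert len(match) + len(mismatch) == len(gendered)
        key = lambda df: set(map(tuple, df[["participant", "trial"]].drop_duplicates().values))
        assert key(match) | key(mismatch) == key(gendered)
        assert not key(match) & key(mismatch)

    def test_mismatch_count_is_14_per_participant(self, default_experiment):
        # 28 gendered trials split evenly over speaker genders by the lists
        _, table, _ = default_experiment
        counts = select_trials(table, "gender_mismatch").groupby("participant")["trial"].nunique()
        assert (counts == 14).all()

    def test_empty_selection_raises(self, tiny_experiment):
        _, table, _ = tiny_experiment
        gendered_only = table[table["item_type"] == "gendered"]
        with pytest.raises(ValidationError, match="no trials"):
            select_trials(gendered_only, "neutral")


def _hand_table():
    """2 participants x 2 gendered trials x 2 bins, fully hand-checkable."""
    rows = []

    def add(pid, pg, item, b, fixated_obj):
        for suffix, role, st in (
            ("tm", "target", "masculine"), ("tf", "target", "feminine"),
            ("dm", "distractor", "masculine"), ("df", "distractor", "feminine"),
        ):
            obj = f"{item}_{suffix}"
            rows.append((pid, pg, item, "gendered", "male", "masculine",
                         b, obj, role, st, int(obj == fixated_obj)))

    add("q1", "male", "g01", 0, "g01_tm")
    add("q1", "male", "g02", 0, "g02_tf")
    add("q1", "male", "g01", 50, "g01_tm")
    add("q1", "male", "g02", 50, "g02_dm")
    add("q2", "female", "g01", 0, "g01_tf")
    add("q2", "female", "g02", 0, None)
    add("q2", "female", "g01", 50, "g01_dm")
    add("q2", "female", "g02", 50, "g02_dm")
    return pd.DataFrame(rows, columns=BINNED_COLUMNS)


class TestProportionCurves:
    def test_hand_computed_compatible_contrast(self):
        curves = proportion_curves(_hand_table(), "compatible_vs_incompatible")
        by = curves.by_participant.set_index(["participant", "bin"])
        # q1 is male: compatible = masculine target
        assert by.loc[("q1", 0), "p_a"] == 0.5 and by.loc[("q1", 0), "n_informative"] == 2
        assert by.loc[("q1", 50), "p_a"] == 1.0
        # q2 is female: compatible = feminine target
        assert by.loc[("q2", 0), "p_a"] == 1.0
        assert np.isnan(by.loc[("q2", 50), "p_a"])  # no target looks at all
        s = curves.summary.set_index("bin")
        assert s.loc[0, "mean"] == pytest.approx(0.75)
        assert s.loc[0, "se"] == pytest.approx(0.25)
        assert s.loc[0, "n"] == 2
        assert s.loc[50, "mean"] == pytest.approx(1.0) and s.loc[50, "n"] == 1

    def test_hand_computed_target_contrast(self):
        curves = proportion_curves(_hand_table(), "targets_vs_distractors")
        by = curves.by_participant.set_index(["participant", "bin"])["p_a"]
        assert by.loc[("q1", 0)] == 1.0 and by.loc[("q1", 50)] == 0.5
        assert by.loc[("q2", 0)] == 1.0 and by.loc[("q2", 50)] == 0.0

    def test_complementary_contrasts_sum_to_one(self, small_experiment):
        _, table, _ = small_experiment
        spec = CONTRASTS["targets_vs_distractors"]
        flipped = ContrastSpec("flipped", set_a=spec.set_b, set_b=spec.set_a)
        a = proportion_curves(table, spec).by_participant.set_index(["participant", "bin"])["p_a"]
        b = proportion_curves(table, flipped).by_participant.set_index(["participant", "bin"])["p_a"]
        both = pd.concat({"a": a, "b": b}, axis=1).dropna()
        assert np.allclose(both["a"] + both["b"], 1.0)

    def test_symmetric_null_hovers_at_half(self, default_experiment):
        # egocentric_effect = 0: both targets equally attractive by design
        _, table, _ = default_experiment
        # gaze persistence autocorrelates bins, so a single experiment's
        # bin-averaged mean scatters by ~0.015 (few effective bins); 4 sigma
        s = proportion_curves(table, "compatible_vs_incompatible").summary
        assert abs(np.nanmean(s["mean"]) - 0.5) < 0.06
        assert np.nanmax(np.abs(s["mean"] - 0.5)) < 0.15

    def test_trial_denominator_counts_all_trials(self):
        curves = proportion_curves(
            _hand_table(), "targets_vs_distractors", denominator="trial"
        )
        by = curves.by_participant.set_index(["participant", "bin"])["p_a"]
        # q2 at bin 50 looked only at distractors: 0 target looks / 2 trials
        assert by.loc[("q2", 50)] == 0.0
        assert by.loc[("q1", 0)] == 1.0  # 2 target looks / 2 trials


class TestComprehension:
    def test_all_correct_gives_one(self):
        trials = [make_trial(item=f"g{i:02d}") for i in range(1, 5)]
        overall, per = comprehension_accuracy(trials)
        assert overall == 1.0 and per.loc["p01"] == 1.0

    def test_one_wrong_of_four(self):
        trials = [make_trial(item=f"g{i:02d}", correct=(i != 1)) for i in range(1, 5)]
        overall, _ = comprehension_accuracy(trials)
        assert overall == 0.75
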