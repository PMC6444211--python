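"""Flanking-comparator selection and nested band classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eship2.exceptions import GradingError
from eship2.model import Cohort
from eship2.pairing import (
    BAND_EDGES,
    FLANKS,
    build_comparisons,
    classify_differences,
    cohort_band_counts,
    per_participant_band1_counts,
)

from conftest import make_session


def session_with_sbp(values: dict[str, float]):
    """A session whose SBP readings at the given slots are overridden."""
    s = make_session(1)
    readings = {
        slot: (
            r
            if slot not in values
            else type(r)(sbp=values[slot], dbp=r.dbp, hr=r.hr)
        )
        for slot, r in s.readings.items()
    }
    return type(s)(profile=s.profile, readings=readings, slot_sources=s.slot_sources)


class TestBuildComparisons:
    def test_identical_flanks_choose_earlier(self):
        s = session_with_sbp({"BP2": 120, "BP1": 120, "BP3": 120})
        pair = build_comparisons(s, "sbp")[0]
        assert (pair.comparator_slot, pair.difference) == ("BP1", 0.0)

    def test_nearer_flank_wins(self):
        # candidates +2 (BP1) and -5 (BP3): the nearer flank is BP1
        s = session_with_sbp({"BP2": 120, "BP1": 118, "BP3": 125})
        pair = build_comparisons(s, "sbp")[0]
        assert (pair.comparator_slot, pair.difference) == ("BP1", 2.0)

    def test_exact_tie_goes_to_earlier_flank(self):
        # candidates +2 (BP3) and -2 (BP5) tie in magnitude: BP3 wins
        s = session_with_sbp({"BP4": 120, "BP3": 118, "BP5": 122})
        pair = build_comparisons(s, "sbp")[1]
        assert pair.device_slot == "BP4"
        assert (pair.comparator_slot, pair.difference) == ("BP3", 2.0)

    def test_forced_flank_rules(self):
        s = session_with_sbp({"BP2": 120, "BP1": 118, "BP3": 125})
        before = build_comparisons(s, "sbp", flank="before")[0]
        after = build_comparisons(s, "sbp", flank="after")[0]
        assert (before.comparator_slot, before.difference) == ("BP1", 2.0)
        assert (after.comparator_slot, after.difference) == ("BP3", -5.0)

    def test_three_pairs_per_session(self):
        pairs = build_comparisons(make_session(1), "hr")
        assert [p.device_slot for p in pairs] == ["BP2", "BP4", "BP6"]
        assert all(p.comparator_slot in FLANKS[p.device_slot] for p in pairs)

    def test_unknown_flank_rule(self):
        with pytest.raises(ValueError):
            build_comparisons(make_session(1), "sbp", flank="random")

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=90, max_value=200), min_size=9, max_size=9))
    def test_nearest_flank_matches_bruteforce(self, sbp_values):
        """Oracle: exhaustive search over both flanks minimizing |difference|."""
        slots = ("BPA", "BPB", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")
        values = dict(zip(slots, map(float, sbp_values)))
        s = session_with_sbp(values)
        for pair in build_comparisons(s, "sbp"):
            before, after = FLANKS[pair.device_slot]
            candidates = [
                (abs(values[pair.device_slot] - values[f]), i, f)
                for i, f in enumerate((before, after))
            ]
            _, _, best = min(candidates)  # ties resolved to the earlier flank
            assert pair.comparator_slot == best
            assert abs(pair.difference) <= min(c[0] for c in candidates)


class TestClassifyDifferences:
    @pytest.mark.parametrize(
        "diffs, edges, expected",
        [
            ([0.0] * 99, (5, 10, 15), (99, 99, 99)),
            ([3, -7, 12, -16], (5, 10, 15), (1, 2, 3)),
            ([-2, 4, 9], (3, 5, 8), (1, 2, 2)),
            ([5, 10, 15], (5, 10, 15), (1, 2, 3)),  # band membership is inclusive
        ],
    )
    def test_cumulative_counts(self, diffs, edges, expected):
        bc = classify_differences(diffs, edges)
        assert bc.counts == expected
        assert bc.n_total == len(diffs)

    def test_empty_input_rejected(self):
        with pytest.raises(GradingError, match="no differences"):
            classify_differences([], (5, 10, 15))

    @pytest.mark.parametrize("edges", [(5, 5, 15), (10, 5, 15), (0, 5, 10), (-1, 5, 10), (5, 10)])
    def test_bad_edges_rejected(self, edges):
        with pytest.raises(GradingError):
            classify_differences([1.0], edges)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-30, 30, allow_nan=False), min_size=1, max_size=50),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, diffs, rnd):
        shuffled = list(diffs)
        rnd.shuffle(shuffled)
        assert classify_differences(diffs, (5, 10, 15)) == classify_differences(
            shuffled, (5, 10, 15)
        )

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-30, 30, allow_nan=False), min_size=1, max_size=50))
    def test_sign_invariance(self, diffs):
        assert classify_differences(diffs, (5, 10, 15)) == classify_differences(
            [-d for d in diffs], (5, 10, 15)
        )


class TestCohortCounts:
    def test_identity_cohort_saturates_all_bands(self, identity_cohort):
        for quantity in ("sbp", "dbp", "hr"):
            bc = cohort_band_counts(identity_cohort, quantity)
            assert bc.counts == (99, 99, 99)
            assert bc.n_total == 99

    def test_single_participant(self):
        cohort = Cohort([make_session(1, sbp_diffs=(2.0, -6.0, 14.0))])
        bc = cohort_band_counts(cohort, "sbp")
        assert (bc.counts, bc.n_total) == ((1, 2, 3), 3)

    def test_two_participants_pooled(self):
        cohort = Cohort([
            make_session(1, sbp_diffs=(0.0, 0.0, 0.0)),
            make_session(2, sbp_diffs=(16.0, 16.0, 16.0)),
        ])
        bc = cohort_band_counts(cohort, "sbp")
        assert (bc.counts, bc.n_total) == ((3, 3, 3), 6)

    def test_per_participant_band1_counts(self):
        cohort = Cohort([
            make_session(1, hr_diffs=(0.0, 2.0, 9.0)),   # 2 within 3 beats/min
            make_session(2, hr_diffs=(4.0, 4.0, 4.0)),   # 0 within
        ])
        assert per_participant_band1_counts(cohort, "hr") == [2, 0]

    def test_hr_edges_differ_from_bp(self):
        assert BAND_EDGES["sbp"] == BAND_EDGES["dbp"] == (5.0, 10.0, 15.0)
        assert BAND_EDGES["hr"] == (3.0, 5.0, 8.0)
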