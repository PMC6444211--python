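"""Part-1/2/3 grading rules against worked examples and a brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eship2.exceptions import GradingError
from eship2.grading import (
    builtin_requirements,
    grade_cohort,
    part1_grade,
    part1_grade_literal,
    part2_grade,
    part3_overall,
    scale_requirements,
)
from eship2.model import Cohort
from eship2.pairing import BandCounts

from conftest import make_session


def bp_counts(counts):
    return BandCounts(band_edges=(5.0, 10.0, 15.0), counts=tuple(counts), n_total=99)


def hr_counts(counts):
    return BandCounts(band_edges=(3.0, 5.0, 8.0), counts=tuple(counts), n_total=99)


BP = builtin_requirements("BP")
HR = builtin_requirements("HR")


class TestRequirementTables:
    def test_bp_table_thresholds(self):
        assert BP.band_edges == (5.0, 10.0, 15.0)
        assert BP.two_of_three == (73, 87, 96)
        assert BP.all_of_three == (65, 81, 93)
        assert BP.part2_min_with_2of3 == 24
        assert BP.part2_max_with_0of3 == 3
        assert (BP.n_pairs, BP.n_participants) == (99, 33)

    def test_hr_extension_table(self):
        assert HR.band_edges == (3.0, 5.0, 8.0)
        # count thresholds carried over from the BP protocol
        assert HR.two_of_three == BP.two_of_three
        assert HR.all_of_three == BP.all_of_three

    def test_unknown_class_rejected(self):
        with pytest.raises(GradingError):
            builtin_requirements("SPO2")


class TestPart1:
    @pytest.mark.parametrize(
        "counts, table, expected",
        [
            ((75, 93, 94), BP, True),   # third band misses the strict row, 2 of 3 suffice
            ((78, 89, 94), BP, True),
            ((89, 91, 93), HR, True),
            ((64, 80, 92), BP, False),  # band 1 below the all-of-three minimum
            ((73, 87, 96), BP, True),   # exactly on the strict row
            ((65, 81, 93), BP, False),  # loose row met everywhere but strict row nowhere
            ((73, 87, 93), BP, True),   # strict in 2 bands, loose in the third
            ((73, 86, 93), BP, False),  # strict in only 1 band
        ],
    )
    def test_two_of_three_and_all_of_three(self, counts, table, expected):
        verdict = part1_grade(bp_counts(counts) if table is BP else hr_counts(counts), table)
        assert verdict.passed is expected
        assert len(verdict.detail) == 6  # both rows for each of the three bands

    def test_mismatched_edges_rejected(self):
        with pytest.raises(GradingError, match="edges"):
            part1_grade(hr_counts((89, 91, 93)), BP)

    def test_mismatched_n_rejected(self):
        small = BandCounts(band_edges=(5.0, 10.0, 15.0), counts=(3, 3, 3), n_total=3)
        with pytest.raises(GradingError, match="scale_requirements"):
            part1_grade(small, BP)

    def test_literal_single_row_reading(self):
        # under the strict row applied to all bands, (75, 93, 94) fails (94 < 96)
        strict = part1_grade_literal(bp_counts((75, 93, 94)), BP, "two_of_three")
        assert not strict.passed
        loose = part1_grade_literal(bp_counts((78, 89, 94)), BP, "all_of_three")
        assert loose.passed
        with pytest.raises(GradingError):
            part1_grade_literal(bp_counts((75, 93, 94)), BP, "median_row")

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(*[st.integers(0, 99)] * 3).map(sorted))
    def test_monotone_in_counts(self, counts):
        """Raising any band count never turns a pass into a fail."""
        base = part1_grade(bp_counts(counts), BP).passed
        for k in range(3):
            bumped = list(counts)
            bumped[k] = min(99, bumped[k] + 1)
            bumped.sort()
            if part1_grade(bp_counts(bumped), BP).passed < base:
                pytest.fail(f"bump at band {k} degraded {counts} -> {bumped}")


class TestPart2:
    @staticmethod
    def participant_counts(n_with_3, n_with_2, n_with_1, n_with_0):
        return [3] * n_with_3 + [2] * n_with_2 + [1] * n_with_1 + [0] * n_with_0

    @pytest.mark.parametrize(
        "n3, n2, n1, n0, expected",
        [
            (20, 9, 1, 3, True),    # 29 with >=2, 3 with 0 (published SBP split)
            (16, 10, 4, 3, True),   # 26 with >=2, 3 with 0
            (25, 5, 3, 0, True),    # 30 with >=2, none with 0
            (13, 10, 10, 0, False), # 23 with >=2: below the minimum of 24
            (14, 10, 5, 4, False),  # 4 with 0: above the maximum of 3
        ],
    )
    def test_min_2of3_and_max_0of3(self, n3, n2, n1, n0, expected):
        counts = self.participant_counts(n3, n2, n1, n0)
        verdict = part2_grade(counts, BP)
        assert verdict.passed is expected

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(GradingError, match="0..3"):
            part2_grade([3] * 32 + [4], BP)

    def test_wrong_length_rejected(self):
        with pytest.raises(GradingError, match="scale_requirements"):
            part2_grade([3] * 10, BP)


class TestPart3:
    def test_conjunction(self):
        p1_pass = part1_grade(bp_counts((75, 93, 94)), BP)
        p1_fail = part1_grade(bp_counts((64, 80, 92)), BP)
        p2_pass = part2_grade([3] * 30 + [1] * 3, BP)
        p2_fail = part2_grade([1] * 33, BP)
        assert part3_overall(p1_pass, p2_pass).passed
        assert not part3_overall(p1_pass, p2_fail).passed
        assert not part3_overall(p1_fail, p2_pass).passed
        assert not part3_overall(p1_fail, p2_fail).passed

    def test_requires_matching_parts(self):
        p1 = part1_grade(bp_counts((75, 93, 94)), BP)
        with pytest.raises(GradingError):
            part3_overall(p1, p1)


class TestScaledCohorts:
    def test_thresholds_scale_conservatively(self):
        table = scale_requirements(BP, 11)  # one third of the standard size
        assert table.scaled
        assert table.n_pairs == 33
        # minima round up, maxima round down
        assert table.two_of_three == (25, 29, 32)
        assert table.all_of_three == (22, 27, 31)
        assert table.part2_min_with_2of3 == 8
        assert table.part2_max_with_0of3 == 1

    def test_standard_size_is_unscaled(self):
        assert scale_requirements(BP, 33) is BP

    def test_grade_cohort_flags_non_standard_size(self):
        cohort = Cohort(make_session(i) for i in range(1, 12))  # identity device, n=11
        result = grade_cohort(cohort, "sbp")
        assert result.table.scaled
        assert result.band_counts.counts == (33, 33, 33)
        assert result.part3.passed
        assert any("non-standard" in n for n in result.part1.notes)


@settings(max_examples=500, deadline=None)
@given(
    st.tuples(*[st.integers(0, 99)] * 3).map(sorted),
    st.lists(st.integers(0, 3), min_size=33, max_size=33),
)
def test_verdicts_match_bruteforce_oracle(counts, participant_counts):
    """Independent literal transcription of the pass rules as the oracle."""
    p1 = part1_grade(bp_counts(counts), BP).passed
    strict_met = sum(c >= t for c, t in zip(counts, (73, 87, 96)))
    loose_met = sum(c >= t for c, t in zip(counts, (65, 81, 93)))
    assert p1 == (strict_met >= 2 and loose_met == 3)

    p2 = part2_grade(participant_counts, BP).passed
    assert p2 == (
        sum(1 for c in participant_counts if c >= 2) >= 24
        and sum(1 for c in participant_counts if c == 0) <= 3
    )
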