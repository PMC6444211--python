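"""Part-1/2/3 verdicts of the ESH-IP2 grading procedure.

Part 1 grades the 99 pooled differences against two rows of minimum counts per
band: the device passes if at least two of the three bands meet the stricter
"two-of-three" row (73/87/96 of 99) AND all three bands meet the looser
"all-of-three" row (65/81/93 of 99). Part 2 grades participants: at least 24 of
33 must have >=2 of their 3 differences within the innermost band, and at most
3 may have none. Part 3 is the conjunction of parts 1 and 2.

The protocol defines these counts for blood pressure only; the heart-rate
extension keeps the count thresholds and substitutes the 3/5/8 beats/min bands.
A "paper-literal" part-1 variant applies a single threshold row to all three
bands of one quantity, for sensitivity reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .exceptions import GradingError
from .model import Cohort, Quantity
from .pairing import (
    BAND_EDGES,
    BandCounts,
    FlankRule,
    cohort_band_counts,
    per_participant_band1_counts,
)

__all__ = [
    "RequirementTable",
    "CriterionResult",
    "PartVerdict",
    "builtin_requirements",
    "scale_requirements",
    "part1_grade",
    "part1_grade_literal",
    "part2_grade",
    "part3_overall",
    "GradingResult",
    "grade_cohort",
]

STANDARD_N_PARTICIPANTS = 33
STANDARD_N_PAIRS = 99

# Minimum counts (of 99) per band: the stricter row must hold in >=2 bands,
# the looser row in all 3.
TWO_OF_THREE = (73, 87, 96)
ALL_OF_THREE = (65, 81, 93)
PART2_MIN_WITH_2OF3 = 24  # of 33 participants
PART2_MAX_WITH_0OF3 = 3


@dataclass(frozen=True)
class RequirementTable:
    """Pass requirements for one quantity class (``BP`` or the ``HR`` extension)."""

    quantity_class: str
    band_edges: tuple[float, float, float]
    two_of_three: tuple[int, int, int] = TWO_OF_THREE
    all_of_three: tuple[int, int, int] = ALL_OF_THREE
    part2_min_with_2of3: int = PART2_MIN_WITH_2OF3
    part2_max_with_0of3: int = PART2_MAX_WITH_0OF3
    n_pairs: int = STANDARD_N_PAIRS
    n_participants: int = STANDARD_N_PARTICIPANTS
    scaled: bool = False

    def __post_init__(self) -> None:
        if any(t < a for t, a in zip(self.two_of_three, self.all_of_three)):
            raise GradingError("two-of-three thresholds must dominate all-of-three")
        if max(self.two_of_three) > self.n_pairs:
            raise GradingError("part-1 thresholds exceed the number of pairs")
        if max(self.part2_min_with_2of3, self.part2_max_with_0of3) > self.n_participants:
            raise GradingError("part-2 thresholds exceed the number of participants")


def builtin_requirements(quantity_class: str) -> RequirementTable:
    """The standard requirement table for ``"BP"`` or the heart-rate extension ``"HR"``."""
    cls = quantity_class.upper()
    if cls not in ("BP", "HR"):
        raise GradingError(f"unknown quantity class {quantity_class!r}; expected 'BP' or 'HR'")
    edges = BAND_EDGES["sbp"] if cls == "BP" else BAND_EDGES["hr"]
    return RequirementTable(quantity_class=cls, band_edges=edges)


def requirements_for(quantity: Quantity) -> RequirementTable:
    return builtin_requirements("HR" if quantity == "hr" else "BP")


def scale_requirements(table: RequirementTable, n_participants: int) -> RequirementTable:
    """Rescale thresholds to a non-standard cohort size (flagged ``scaled``).

    Minimum counts scale by ``n/33`` rounded up, maxima rounded down, so a
    smaller cohort never passes more easily than the standard one.
    """
    if n_participants < 1:
        raise GradingError("n_participants must be >= 1")
    if n_participants == table.n_participants:
        return table
    f = n_participants / STANDARD_N_PARTICIPANTS
    up = lambda x: math.ceil(x * f)
    down = lambda x: math.floor(x * f)
    return replace(
        table,
        two_of_three=tuple(up(t) for t in table.two_of_three),
        all_of_three=tuple(up(t) for t in table.all_of_three),
        part2_min_with_2of3=up(table.part2_min_with_2of3),
        part2_max_with_0of3=down(table.part2_max_with_0of3),
        n_pairs=3 * n_participants,
        n_participants=n_participants,
        scaled=True,
    )


@dataclass(frozen=True)
class CriterionResult:
    name: str
    achieved: int
    required: int
    kind: str  # "min" (achieved >= required) or "max" (achieved <= required)
    passed: bool


@dataclass(frozen=True)
class PartVerdict:
    part: int
    passed: bool
    detail: tuple[CriterionResult, ...]
    notes: tuple[str, ...] = ()


def _check_table(band_counts: BandCounts, table: RequirementTable) -> None:
    if band_counts.band_edges != table.band_edges:
        raise GradingError(
            f"band edges {band_counts.band_edges} do not match the requirement "
            f"table's {table.band_edges}"
        )
    if band_counts.n_total != table.n_pairs:
        raise GradingError(
            f"{band_counts.n_total} differences but the table expects "
            f"{table.n_pairs}; use scale_requirements() for non-standard cohorts"
        )


def part1_grade(band_counts: BandCounts, table: RequirementTable) -> PartVerdict:
    """Per-measurement verdict: >=2 bands meet the stricter row and all 3 the looser row."""
    _check_table(band_counts, table)
    detail = []
    n_strict = 0
    all_loose = True
    for edge, achieved, strict, loose in zip(
        band_counts.band_edges, band_counts.counts, table.two_of_three, table.all_of_three
    ):
        ok_strict = achieved >= strict
        ok_loose = achieved >= loose
        n_strict += ok_strict
        all_loose &= ok_loose
        detail.append(CriterionResult(
            f"band<={edge:g}: two-of-three row", achieved, strict, "min", ok_strict))
        detail.append(CriterionResult(
            f"band<={edge:g}: all-of-three row", achieved, loose, "min", ok_loose))
    passed = n_strict >= 2 and all_loose
    notes = (f"{n_strict} of 3 bands meet the two-of-three row (need >=2)",)
    if table.scaled:
        notes += ("non-standard cohort size: thresholds rescaled",)
    return PartVerdict(part=1, passed=passed, detail=tuple(detail), notes=notes)


def part1_grade_literal(
    band_counts: BandCounts, table: RequirementTable, row: str
) -> PartVerdict:
    """Literal-reading variant: one threshold row applied to all three bands.

    ``row`` selects ``"two_of_three"`` or ``"all_of_three"``. Under this
    reading a quantity passes only if every band meets the selected row.
    Provided for sensitivity reporting; the standard semantics is
    :func:`part1_grade`.
    """
    _check_table(band_counts, table)
    if row not in ("two_of_three", "all_of_three"):
        raise GradingError(f"row must be 'two_of_three' or 'all_of_three', got {row!r}")
    thresholds = getattr(table, row)
    detail = tuple(
        CriterionResult(f"band<={edge:g}: literal row", achieved, req, "min", achieved >= req)
        for edge, achieved, req in zip(band_counts.band_edges, band_counts.counts, thresholds)
    )
    passed = all(c.passed for c in detail)
    return PartVerdict(
        part=1, passed=passed, detail=detail,
        notes=(f"literal single-row semantics ({row})",),
    )


def part2_grade(
    per_participant_band1_counts: Sequence[int], table: RequirementTable
) -> PartVerdict:
    """Per-participant verdict on innermost-band counts (each in 0..3)."""
    counts = list(per_participant_band1_counts)
    bad = [c for c in counts if c not in (0, 1, 2, 3)]
    if bad:
        raise GradingError(f"per-participant counts must be in 0..3, got {bad}")
    if len(counts) != table.n_participants:
        raise GradingError(
            f"{len(counts)} participants but the table expects {table.n_participants}; "
            f"use scale_requirements() for non-standard cohorts"
        )
    n_with_2of3 = sum(1 for c in counts if c >= 2)
    n_with_0of3 = sum(1 for c in counts if c == 0)
    detail = (
        CriterionResult(
            "participants with >=2 of 3 in band 1", n_with_2of3,
            table.part2_min_with_2of3, "min", n_with_2of3 >= table.part2_min_with_2of3),
        CriterionResult(
            "participants with 0 of 3 in band 1", n_with_0of3,
            table.part2_max_with_0of3, "max", n_with_0of3 <= table.part2_max_with_0of3),
    )
    notes = ("non-standard cohort size: thresholds rescaled",) if table.scaled else ()
    return PartVerdict(
        part=2, passed=all(c.passed for c in detail), detail=detail, notes=notes
    )


def part3_overall(part1: PartVerdict, part2: PartVerdict) -> PartVerdict:
    """Overall verdict: pass iff parts 1 and 2 both passed."""
    if (part1.part, part2.part) != (1, 2):
        raise GradingError("part3_overall expects a part-1 and a part-2 verdict")
    detail = (
        CriterionResult("part 1 passed", int(part1.passed), 1, "min", part1.passed),
        CriterionResult("part 2 passed", int(part2.passed), 1, "min", part2.passed),
    )
    return PartVerdict(part=3, passed=part1.passed and part2.passed, detail=detail)


@dataclass(frozen=True)
class GradingResult:
    """Full grading of one quantity over a cohort."""

    quantity: Quantity
    table: RequirementTable
    band_counts: BandCounts
    per_participant_band1: tuple[int, ...]
    part1: PartVerdict
    part2: PartVerdict
    part3: PartVerdict


def grade_cohort(
    cohort: Cohort, quantity: Quantity, flank: FlankRule = "nearest"
) -> GradingResult:
    """Run pairing, band classification, and the three grading parts for one quantity.

    Cohorts of non-standard size are graded against proportionally rescaled
    thresholds and the result's table is flagged ``scaled``.
    """
    table = requirements_for(quantity)
    if len(cohort) != table.n_participants:
        table = scale_requirements(table, len(cohort))
    counts = cohort_band_counts(cohort, quantity, flank)
    band1 = per_participant_band1_counts(cohort, quantity, flank)
    p1 = part1_grade(counts, table)
    p2 = part2_grade(band1, table)
    return GradingResult(
        quantity=quantity, table=table, band_counts=counts,
        per_participant_band1=tuple(band1), part1=p1, part2=p2,
        part3=part3_overall(p1, p2),
    )
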