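"""Device/reference comparison pairing and nested error-band classification.

Each of the three graded test-device readings (BP2, BP4, BP6) is compared with
its two flanking reference readings (BP1/BP3, BP3/BP5, BP5/BP7). By default the
nearer flank — the one with the smaller absolute difference — supplies the
graded comparison, giving exactly three difference pairs per participant per
quantity (99 for a standard 33-participant cohort). Absolute differences are
then counted within three nested bands (5/10/15 mm Hg for pressure, 3/5/8
beats/min for heart rate); band membership is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import GradingError
from .model import (
    GRADED_TEST_SLOTS,
    Cohort,
    Quantity,
    SessionRecord,
    validate_session,
)

__all__ = [
    "BAND_EDGES",
    "FLANKS",
    "FlankRule",
    "ComparisonPair",
    "BandCounts",
    "build_comparisons",
    "session_differences",
    "cohort_comparisons",
    "classify_differences",
    "cohort_band_counts",
    "per_participant_band1_counts",
]

#: Nested band half-widths per quantity (pressure in mm Hg, heart rate in beats/min).
BAND_EDGES: dict[str, tuple[float, float, float]] = {
    "sbp": (5.0, 10.0, 15.0),
    "dbp": (5.0, 10.0, 15.0),
    "hr": (3.0, 5.0, 8.0),
}

#: Flanking reference slots for each graded test-device slot, in schedule order.
FLANKS: dict[str, tuple[str, str]] = {
    "BP2": ("BP1", "BP3"),
    "BP4": ("BP3", "BP5"),
    "BP6": ("BP5", "BP7"),
}

#: Comparator-selection rules: the earlier flank, the later flank, or whichever
#: is nearer in absolute difference (protocol default; ties go to the earlier).
FlankRule = str  # "nearest" | "before" | "after"
_FLANK_RULES = ("nearest", "before", "after")


@dataclass(frozen=True)
class ComparisonPair:
    """One graded device reading, its selected reference comparator, and the signed difference."""

    quantity: Quantity
    device_slot: str
    device_value: float
    comparator_slot: str
    comparator_value: float
    difference: float  # signed, device - reference

    @property
    def pair_mean(self) -> float:
        """Mean of the two readings — the x coordinate of a Bland-Altman point."""
        return 0.5 * (self.device_value + self.comparator_value)


def build_comparisons(
    session: SessionRecord,
    quantity: Quantity,
    flank: FlankRule = "nearest",
) -> list[ComparisonPair]:
    """The three graded comparisons of a session for one quantity.

    With ``flank="nearest"`` the comparator is the flanking reference reading
    with the smaller absolute difference; an exact tie selects the earlier
    (lower-numbered) flank. ``"before"``/``"after"`` force a fixed flank.
    """
    if flank not in _FLANK_RULES:
        raise ValueError(f"flank must be one of {_FLANK_RULES}, got {flank!r}")
    validate_session(session)

    pairs = []
    for device_slot in GRADED_TEST_SLOTS:
        device_value = getattr(session.readings[device_slot], quantity)
        before, after = FLANKS[device_slot]
        if flank == "before":
            chosen = before
        elif flank == "after":
            chosen = after
        else:
            d_before = device_value - getattr(session.readings[before], quantity)
            d_after = device_value - getattr(session.readings[after], quantity)
            # strict <: an exact tie keeps the earlier flank
            chosen = after if abs(d_after) < abs(d_before) else before
        comparator_value = getattr(session.readings[chosen], quantity)
        pairs.append(
            ComparisonPair(
                quantity=quantity,
                device_slot=device_slot,
                device_value=device_value,
                comparator_slot=chosen,
                comparator_value=comparator_value,
                difference=device_value - comparator_value,
            )
        )
    return pairs


def session_differences(
    session: SessionRecord, quantity: Quantity, flank: FlankRule = "nearest"
) -> list[float]:
    return [p.difference for p in build_comparisons(session, quantity, flank)]


def cohort_comparisons(
    cohort: Cohort, quantity: Quantity, flank: FlankRule = "nearest"
) -> list[ComparisonPair]:
    """All graded comparisons pooled over the cohort, in session order."""
    pairs: list[ComparisonPair] = []
    for session in cohort:
        pairs.extend(build_comparisons(session, quantity, flank))
    return pairs


@dataclass(frozen=True)
class BandCounts:
    """Cumulative counts of absolute differences within three nested bands."""

    band_edges: tuple[float, float, float]
    counts: tuple[int, int, int]
    n_total: int

    def __post_init__(self) -> None:
        if not (self.counts[0] <= self.counts[1] <= self.counts[2] <= self.n_total):
            raise GradingError(
                f"band counts must be non-decreasing and <= n_total: "
                f"{self.counts} with n_total={self.n_total}"
            )


def classify_differences(
    differences: Iterable[float],
    band_edges: Sequence[float],
) -> BandCounts:
    """Count how many |difference| fall within each nested band (inclusive)."""
    diffs = list(differences)
    if not diffs:
        raise GradingError("no differences to classify")
    edges = tuple(float(e) for e in band_edges)
    if len(edges) != 3 or not (0 < edges[0] < edges[1] < edges[2]):
        raise GradingError(
            f"band edges must be three strictly increasing positive values, got {edges}"
        )
    counts = tuple(sum(1 for d in diffs if abs(d) <= e) for e in edges)
    return BandCounts(band_edges=edges, counts=counts, n_total=len(diffs))


def cohort_band_counts(
    cohort: Cohort, quantity: Quantity, flank: FlankRule = "nearest"
) -> BandCounts:
    """Pooled band classification over all participants (3 differences each)."""
    diffs = [p.difference for p in cohort_comparisons(cohort, quantity, flank)]
    return classify_differences(diffs, BAND_EDGES[quantity])


def per_participant_band1_counts(
    cohort: Cohort, quantity: Quantity, flank: FlankRule = "nearest"
) -> list[int]:
    """Per participant, how many of their 3 differences lie within the innermost band."""
    edge = BAND_EDGES[quantity][0]
    return [
        sum(1 for d in session_differences(s, quantity, flank) if abs(d) <= edge)
        for s in cohort
    ]
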