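"""Domain model for ESH-IP2 validation sessions.

A validation session is an ordered schedule of nine measurements taken on one
participant: an entry pair (``BPA`` on the reference device, ``BPB`` on the test
device, both discarded from grading) followed by seven alternating readings
``BP1``..``BP7`` that start and end on the reference device. Each measurement is
a (systolic, diastolic, heart-rate) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .exceptions import ReadingError, ScheduleError

__all__ = [
    "SLOT_ORDER",
    "REFERENCE_SLOTS",
    "TEST_SLOTS",
    "ENTRY_SLOTS",
    "GRADED_TEST_SLOTS",
    "EXPECTED_SOURCES",
    "HR_PLAUSIBLE_WINDOW",
    "SBP_DEVICE_RANGE",
    "CUFF_RANGE_MM",
    "Quantity",
    "QUANTITIES",
    "TriplexReading",
    "ParticipantProfile",
    "SessionRecord",
    "Cohort",
    "compute_bmi",
    "plausibility_warnings",
    "session_problems",
    "validate_session",
    "EligibilityCheck",
    "EligibilityReport",
    "validate_cohort",
]

#: The nine measurement slots in protocol order.
SLOT_ORDER: tuple[str, ...] = (
    "BPA", "BPB", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)

REFERENCE_SLOTS = frozenset({"BPA", "BP1", "BP3", "BP5", "BP7"})
TEST_SLOTS = frozenset({"BPB", "BP2", "BP4", "BP6"})

#: Entry/familiarization readings, excluded from grading.
ENTRY_SLOTS: tuple[str, str] = ("BPA", "BPB")

#: Test-device slots that enter the grading (three per participant).
GRADED_TEST_SLOTS: tuple[str, str, str] = ("BP2", "BP4", "BP6")

EXPECTED_SOURCES: dict[str, str] = {
    slot: ("reference" if slot in REFERENCE_SLOTS else "test") for slot in SLOT_ORDER
}

#: Plausibility window for heart rate, beats/min (test-device measuring range).
HR_PLAUSIBLE_WINDOW: tuple[float, float] = (40.0, 180.0)

#: Pressure measuring range of the test device, mm Hg.
SBP_DEVICE_RANGE: tuple[float, float] = (0.0, 300.0)

#: Arm circumferences covered by the cuff, mm.
CUFF_RANGE_MM: tuple[float, float] = (220.0, 420.0)

Quantity = Literal["sbp", "dbp", "hr"]
QUANTITIES: tuple[Quantity, ...] = ("sbp", "dbp", "hr")


@dataclass(frozen=True)
class TriplexReading:
    """One measurement event: systolic and diastolic pressure (mm Hg), heart rate (beats/min)."""

    sbp: float
    dbp: float
    hr: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ReadingError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        if self.sbp > SBP_DEVICE_RANGE[1]:
            raise ReadingError(
                f"sbp={self.sbp} outside device pressure range {SBP_DEVICE_RANGE}"
            )
        if self.hr <= 0:
            raise ReadingError(f"hr={self.hr} must be positive")


def plausibility_warnings(
    reading: TriplexReading,
    hr_window: tuple[float, float] = HR_PLAUSIBLE_WINDOW,
) -> list[str]:
    """Soft checks (warnings, not errors) against device measuring windows."""
    warnings = []
    lo, hi = hr_window
    if not (lo <= reading.hr <= hi):
        warnings.append(f"hr={reading.hr} outside plausibility window {lo}-{hi} beats/min")
    return warnings


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index (Quetelet index): weight [kg] / (height [m])^2.

    Raises
    ------
    ValueError
        If weight or height is non-positive.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if height_cm <= 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    height_m = height_cm / 100.0
    return weight_kg / height_m**2


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and exclusion flags for one participant.

    ``arm_circumference`` is in millimetres; cuff sizing is checked as a
    warning during cohort eligibility, not as a construction error.
    """

    id: str
    sex: Literal["male", "female"]
    age: float
    weight: float  # kg
    height: float  # cm
    arm_circumference: float  # mm
    excluded_arrhythmia: bool = False
    excluded_circulatory: bool = False
    excluded_pregnant: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "weight", "height", "arm_circumference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)

    @property
    def has_exclusion(self) -> bool:
        return (
            self.excluded_arrhythmia
            or self.excluded_circulatory
            or self.excluded_pregnant
        )


@dataclass(frozen=True)
class SessionRecord:
    """A participant's profile plus the ordered nine-slot measurement schedule."""

    profile: ParticipantProfile
    readings: Mapping[str, TriplexReading]
    slot_sources: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_readings(
        cls, profile: ParticipantProfile, readings: Mapping[str, TriplexReading]
    ) -> "SessionRecord":
        """Build a session with the standard protocol source tags."""
        return cls(profile=profile, readings=dict(readings), slot_sources=dict(EXPECTED_SOURCES))


def session_problems(session: SessionRecord) -> list[str]:
    """All schedule violations of a session (empty list means valid)."""
    problems = []
    slots = set(session.readings)
    missing = [s for s in SLOT_ORDER if s not in slots]
    extra = sorted(slots - set(SLOT_ORDER))
    if missing:
        problems.append(f"missing slots: {', '.join(missing)}")
    if extra:
        problems.append(f"unknown slots: {', '.join(extra)}")
    for slot in SLOT_ORDER:
        if slot not in session.slot_sources:
            problems.append(f"slot {slot}: no device-source tag")
        elif session.slot_sources[slot] != EXPECTED_SOURCES[slot]:
            problems.append(
                f"slot {slot}: source {session.slot_sources[slot]!r}, "
                f"protocol requires {EXPECTED_SOURCES[slot]!r}"
            )
    return problems


def validate_session(session: SessionRecord) -> None:
    """Raise :class:`ScheduleError` if the session violates the protocol schedule."""
    problems = session_problems(session)
    if problems:
        raise ScheduleError(
            f"session {session.profile.id}: " + "; ".join(problems)
        )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of validation sessions with unique participant ids."""

    sessions: tuple[SessionRecord, ...]

    def __init__(self, sessions: Iterable[SessionRecord]):
        object.__setattr__(self, "sessions", tuple(sessions))
        ids = [s.profile.id for s in self.sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)


# Recruitment requirements of the protocol.
MIN_PARTICIPANTS = 33
MIN_PER_SEX = 10
MIN_AGE = 25.0


@dataclass(frozen=True)
class EligibilityCheck:
    name: str
    passed: bool
    reason: str  # e.g. "n_male < 10" when failed, "n_male >= 10" when passed
    achieved: float
    required: float


@dataclass(frozen=True)
class EligibilityReport:
    n_total: int
    n_male: int
    n_female: int
    checks: tuple[EligibilityCheck, ...]
    warnings: tuple[str, ...]

    @property
    def eligible(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def reasons(self) -> list[str]:
        return [c.reason for c in self.checks if not c.passed]


def validate_cohort(cohort: Cohort) -> EligibilityReport:
    """Check the cohort against the protocol's recruitment requirements.

    Requirements: at least 33 evaluable participants, of whom at least 10 men
    and 10 women, all at least 25 years old and free of the exclusion criteria
    (sustained arrhythmia, circulatory problems contraindicating the cuff,
    pregnancy). Cuff-fit (arm circumference 220-420 mm) is reported as a
    warning only. Returns structured findings; it never raises.
    """
    n_total = len(cohort)
    n_male = sum(1 for s in cohort if s.profile.sex == "male")
    n_female = n_total - n_male
    n_underage = sum(1 for s in cohort if s.profile.age < MIN_AGE)
    n_excluded = sum(1 for s in cohort if s.profile.has_exclusion)

    def _check(name, achieved, required, op) -> EligibilityCheck:
        if op == ">=":
            ok = achieved >= required
            sym = ">=" if ok else "<"
        else:  # "=="
            ok = achieved == required
            sym = "==" if ok else "!="
        return EligibilityCheck(
            name=name, passed=ok, reason=f"{name} {sym} {required:g}",
            achieved=achieved, required=required,
        )

    checks = (
        _check("n_total", n_total, MIN_PARTICIPANTS, ">="),
        _check("n_male", n_male, MIN_PER_SEX, ">="),
        _check("n_female", n_female, MIN_PER_SEX, ">="),
        _check("n_age_below_25", n_underage, 0, "=="),
        _check("n_with_exclusion", n_excluded, 0, "=="),
    )

    warnings = []
    lo, hi = CUFF_RANGE_MM
    for s in cohort:
        arm = s.profile.arm_circumference
        if not (lo <= arm <= hi):
            warnings.append(
                f"participant {s.profile.id}: arm circumference {arm:g} mm outside "
                f"cuff range {lo:g}-{hi:g} mm"
            )
        for slot, reading in s.readings.items():
            for w in plausibility_warnings(reading):
                warnings.append(f"participant {s.profile.id} slot {slot}: {w}")

    return EligibilityReport(
        n_total=n_total, n_male=n_male, n_female=n_female,
        checks=checks, warnings=tuple(warnings),
    )
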