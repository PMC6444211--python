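"""Shared fixtures: hand-built sessions with prescribed device-reference differences."""

from __future__ import annotations

import pytest

from eship2.model import (
    SLOT_ORDER,
    Cohort,
    ParticipantProfile,
    SessionRecord,
    TriplexReading,
)
from eship2.simulate import SimulationConfig, simulate_cohort

# reference levels used by the constructed sessions
REF_SBP, REF_DBP, REF_HR = 120.0, 80.0, 70.0


def make_profile(i: int, sex: str | None = None, **overrides) -> ParticipantProfile:
    fields = dict(
        id=f"S{i:03d}",
        sex=sex or ("male" if i <= 13 else "female"),
        age=30.0 + (i % 40),
        weight=70.0 + (i % 15),
        height=165.0 + (i % 10),
        arm_circumference=280.0 + (i % 30),
    )
    fields.update(overrides)
    return ParticipantProfile(**fields)


def make_session(
    i: int,
    sbp_diffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    dbp_diffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    hr_diffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    **profile_overrides,
) -> SessionRecord:
    """A session whose reference readings are constant, so both flanks of each
    test slot are equal and the graded difference is exactly the requested one."""
    readings = {}
    device_slots = {"BP2": 0, "BP4": 1, "BP6": 2}
    for slot in SLOT_ORDER:
        if slot in device_slots:
            k = device_slots[slot]
            readings[slot] = TriplexReading(
                sbp=REF_SBP + sbp_diffs[k],
                dbp=REF_DBP + dbp_diffs[k],
                hr=REF_HR + hr_diffs[k],
            )
        else:
            readings[slot] = TriplexReading(sbp=REF_SBP, dbp=REF_DBP, hr=REF_HR)
    return SessionRecord.from_readings(make_profile(i, **profile_overrides), readings)


def cohort_from_differences(sbp_diffs_per_participant) -> Cohort:
    """A 13-men/20-women eligible cohort realizing the given SBP differences."""
    return Cohort(
        make_session(i + 1, sbp_diffs=tuple(d))
        for i, d in enumerate(sbp_diffs_per_participant)
    )


#: Per-participant SBP differences realizing the published achieved pattern:
#: band counts (75, 93, 94) of 99, with 29 participants having >=2 of 3 within
#: 5 mm Hg and 3 participants having none.
PUBLISHED_SBP_PATTERN = (
    [(0.0, 2.0, -4.0)] * 16          # all three within 5
    + [(0.0, 3.0, 8.0)] * 10         # two within 5, one in (5, 10]
    + [(0.0, 3.0, 20.0)] * 3         # two within 5, one beyond 15
    + [(4.0, 8.0, 20.0)]             # one within 5
    + [(8.0, 8.0, 8.0)] * 2          # none within 5
    + [(8.0, 13.0, 20.0)]            # none within 5
)


@pytest.fixture(scope="session")
def identity_config() -> SimulationConfig:
    """All noise, drift, and device bias set to zero: test readings equal reference."""
    cfg = SimulationConfig(seed=7)
    return cfg.with_device(sbp_bias=0.0, dbp_bias=0.0, hr_bias=0.0,
                           noise_scale=0.0, drift_scale=0.0)


@pytest.fixture(scope="session")
def identity_cohort(identity_config) -> Cohort:
    return simulate_cohort(identity_config)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def published_pattern_cohort() -> Cohort:
    return cohort_from_differences(PUBLISHED_SBP_PATTERN)
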