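"""Synthetic validation sessions with the structure the grading analysis assumes.

Generative model, per participant and quantity (SBP, DBP, HR):

* a latent true level drawn from a between-subject normal distribution;
* a within-subject random walk across the nine measurement slots (step SD
  ``drift_sd``), emulating the physiological variability between consecutive
  readings;
* reference slots observe latent + observer noise;
* test-device slots observe ``bias_add + bias_mult * latent`` + device noise.

Physiological coherence is enforced after noise: diastolic stays below
systolic, heart rate stays inside its plausibility window, systolic inside the
device pressure range. With ``rounding="integer"`` readings are rounded to
whole units as oscillometric displays report them.

A single integer seed drives a hierarchical scheme (cohort seed -> one child
stream per participant, draws in fixed slot order within a participant), so the
same seed always reproduces the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConfigError
from .grading import grade_cohort
from .model import (
    HR_PLAUSIBLE_WINDOW,
    SBP_DEVICE_RANGE,
    SLOT_ORDER,
    Cohort,
    ParticipantProfile,
    Quantity,
    SessionRecord,
    TriplexReading,
)
from .pairing import FLANKS, GRADED_TEST_SLOTS, FlankRule, build_comparisons

__all__ = [
    "TruncNormSpec",
    "QuantityModel",
    "SimulationConfig",
    "simulate_cohort",
    "DeviceParamEstimate",
    "estimate_device_params",
    "PassProbability",
    "pass_probability",
]


@dataclass(frozen=True)
class TruncNormSpec:
    """A normal distribution truncated to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigError(f"{name}: sd must be >= 0, got {self.sd}")
        if not self.lo < self.hi:
            raise ConfigError(f"{name}: need lo < hi, got [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        # rejection sampling; bounds are several SDs wide for all defaults
        x = rng.normal(self.mean, self.sd, size=size)
        out = np.clip(x, self.lo, self.hi)
        return out


@dataclass(frozen=True)
class QuantityModel:
    """Between-subject, within-subject, and device-error model for one quantity."""

    mean: float
    between_sd: float
    drift_sd: float  # random-walk step SD per slot
    observer_noise_sd: float
    device_bias_add: float  # a in a + b * true
    device_bias_mult: float  # b
    device_noise_sd: float
    lo: float  # plausibility clip after noise
    hi: float

    def validate(self, name: str) -> None:
        for f in ("between_sd", "drift_sd", "observer_noise_sd", "device_noise_sd"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{name}.{f} must be >= 0, got {getattr(self, f)}")
        if not self.lo < self.hi:
            raise ConfigError(f"{name}: need lo < hi, got [{self.lo}, {self.hi}]")


def _default_age() -> TruncNormSpec:
    return TruncNormSpec(47.94, 17.21, 25.0, 87.0)


def _default_weight() -> TruncNormSpec:
    return TruncNormSpec(72.45, 10.47, 54.0, 92.0)


def _default_height() -> TruncNormSpec:
    return TruncNormSpec(167.06, 5.51, 158.0, 178.0)


def _default_arm() -> TruncNormSpec:
    return TruncNormSpec(285.76, 21.80, 230.0, 320.0)


def _default_sbp() -> QuantityModel:
    return QuantityModel(
        mean=125.0, between_sd=15.0, drift_sd=2.0, observer_noise_sd=2.0,
        device_bias_add=3.0, device_bias_mult=1.0, device_noise_sd=3.5,
        lo=70.0, hi=SBP_DEVICE_RANGE[1],
    )


def _default_dbp() -> QuantityModel:
    return QuantityModel(
        mean=75.0, between_sd=10.0, drift_sd=1.5, observer_noise_sd=2.0,
        device_bias_add=3.0, device_bias_mult=1.0, device_noise_sd=3.5,
        lo=40.0, hi=150.0,
    )


def _default_hr() -> QuantityModel:
    return QuantityModel(
        mean=72.0, between_sd=10.0, drift_sd=1.5, observer_noise_sd=1.0,
        device_bias_add=1.5, device_bias_mult=1.0, device_noise_sd=2.5,
        lo=HR_PLAUSIBLE_WINDOW[0], hi=HR_PLAUSIBLE_WINDOW[1],
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated validation study.

    Defaults reproduce the standard protocol cohort (33 participants, 13 men /
    20 women) with demographics anchored to a general-population validation
    sample and a mildly biased but passing test device.
    """

    n_participants: int = 33
    n_male: int = 13
    age: TruncNormSpec = field(default_factory=_default_age)
    weight: TruncNormSpec = field(default_factory=_default_weight)
    height: TruncNormSpec = field(default_factory=_default_height)
    arm_circumference: TruncNormSpec = field(default_factory=_default_arm)
    sbp: QuantityModel = field(default_factory=_default_sbp)
    dbp: QuantityModel = field(default_factory=_default_dbp)
    hr: QuantityModel = field(default_factory=_default_hr)
    min_pulse_pressure: float = 20.0  # latent SBP-DBP floor, mm Hg
    rounding: str = "integer"  # "integer" | "none"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError(f"n_participants must be >= 1, got {self.n_participants}")
        if not 0 <= self.n_male <= self.n_participants:
            raise ConfigError(
                f"n_male must be in 0..n_participants, got {self.n_male}"
            )
        if self.rounding not in ("integer", "none"):
            raise ConfigError(f"rounding must be 'integer' or 'none', got {self.rounding!r}")
        if self.min_pulse_pressure <= 0:
            raise ConfigError("min_pulse_pressure must be positive")
        for name in ("age", "weight", "height", "arm_circumference"):
            getattr(self, name).validate(name)
        for name in ("sbp", "dbp", "hr"):
            getattr(self, name).validate(name)

    def with_device(
        self,
        sbp_bias: float | None = None,
        dbp_bias: float | None = None,
        hr_bias: float | None = None,
        noise_scale: float | None = None,
        drift_scale: float | None = None,
    ) -> "SimulationConfig":
        """Convenience copy with modified device bias / noise / drift settings."""
        new = {}
        for name, bias in (("sbp", sbp_bias), ("dbp", dbp_bias), ("hr", hr_bias)):
            qm = getattr(self, name)
            if bias is not None:
                qm = replace(qm, device_bias_add=bias)
            if noise_scale is not None:
                qm = replace(
                    qm,
                    device_noise_sd=qm.device_noise_sd * noise_scale,
                    observer_noise_sd=qm.observer_noise_sd * noise_scale,
                )
            if drift_scale is not None:
                qm = replace(qm, drift_sd=qm.drift_sd * drift_scale)
            new[name] = qm
        return replace(self, **new)


def _simulate_quantity(
    rng: np.random.Generator, qm: QuantityModel, is_test_slot: np.ndarray
) -> np.ndarray:
    """Observed values over the 9 slots for one participant and one quantity."""
    true = rng.normal(qm.mean, qm.between_sd)
    steps = rng.normal(0.0, qm.drift_sd, size=len(SLOT_ORDER))
    steps[0] = 0.0
    latent = true + np.cumsum(steps)
    obs = np.where(
        is_test_slot,
        qm.device_bias_add + qm.device_bias_mult * latent
        + rng.normal(0.0, qm.device_noise_sd, size=len(SLOT_ORDER)),
        latent + rng.normal(0.0, qm.observer_noise_sd, size=len(SLOT_ORDER)),
    )
    return obs


def _simulate_session(
    rng: np.random.Generator, config: SimulationConfig, pid: str, sex: str
) -> SessionRecord:
    profile = ParticipantProfile(
        id=pid,
        sex=sex,
        age=float(config.age.draw(rng)),
        weight=float(config.weight.draw(rng)),
        height=float(config.height.draw(rng)),
        arm_circumference=float(config.arm_circumference.draw(rng)),
    )
    is_test = np.array([s not in ("BPA", "BP1", "BP3", "BP5", "BP7") for s in SLOT_ORDER])

    sbp = _simulate_quantity(rng, config.sbp, is_test)
    dbp = _simulate_quantity(rng, config.dbp, is_test)
    hr = _simulate_quantity(rng, config.hr, is_test)

    # physiological coherence: DBP below SBP, everything inside plausibility clips
    dbp = np.minimum(dbp, sbp - config.min_pulse_pressure / 2.0)
    dbp = np.clip(dbp, config.dbp.lo, config.dbp.hi)
    sbp = np.clip(sbp, np.maximum(config.sbp.lo, dbp + 1.0), config.sbp.hi)
    hr = np.clip(hr, config.hr.lo, config.hr.hi)
    if config.rounding == "integer":
        sbp, dbp, hr = np.rint(sbp), np.rint(dbp), np.rint(hr)
        sbp = np.maximum(sbp, dbp + 1.0)  # rounding may not collapse the pair

    readings = {
        slot: TriplexReading(sbp=float(sbp[i]), dbp=float(dbp[i]), hr=float(hr[i]))
        for i, slot in enumerate(SLOT_ORDER)
    }
    return SessionRecord.from_readings(profile, readings)


def simulate_cohort(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> Cohort:
    """Generate a full cohort of validation sessions.

    ``seed`` overrides ``config.seed``; a :class:`numpy.random.SeedSequence`
    may be passed directly (used internally by :func:`pass_probability`).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_participants)
    sessions = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sex = "male" if i < config.n_male else "female"
        sessions.append(_simulate_session(rng, config, pid=f"P{i + 1:03d}", sex=sex))
    return Cohort(sessions)


@dataclass(frozen=True)
class DeviceParamEstimate:
    """Estimated additive device bias and difference SD, with standard errors."""

    quantity: Quantity
    bias: float
    bias_se: float
    error_sd: float
    error_sd_se: float
    n: int
    comparator: str


def estimate_device_params(
    cohort: Cohort,
    quantity: Quantity,
    comparator: str = "flank-mean",
) -> DeviceParamEstimate:
    """Recover the device's additive bias and error SD from graded readings.

    ``comparator="flank-mean"`` differences each test reading against the mean
    of its two flanking reference readings, which is unbiased for the additive
    bias under the symmetric random-walk drift model; ``"nearest"``,
    ``"before"`` and ``"after"`` use the corresponding single-flank pairing
    (nearest-flank selection shrinks the apparent bias toward zero). Standard
    errors treat the differences as independent, which slightly understates
    uncertainty because consecutive differences share reference readings.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 participants to estimate device parameters")
    diffs: list[float] = []
    if comparator == "flank-mean":
        for session in cohort:
            for device_slot in GRADED_TEST_SLOTS:
                device = getattr(session.readings[device_slot], quantity)
                before, after = FLANKS[device_slot]
                ref = 0.5 * (
                    getattr(session.readings[before], quantity)
                    + getattr(session.readings[after], quantity)
                )
                diffs.append(device - ref)
    elif comparator in ("nearest", "before", "after"):
        for session in cohort:
            diffs.extend(
                p.difference for p in build_comparisons(session, quantity, comparator)
            )
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    d = np.asarray(diffs)
    n = len(d)
    sd = float(d.std(ddof=1))
    return DeviceParamEstimate(
        quantity=quantity,
        bias=float(d.mean()),
        bias_se=sd / np.sqrt(n),
        error_sd=sd,
        error_sd_se=sd / np.sqrt(2 * (n - 1)),
        n=n,
        comparator=comparator,
    )


@dataclass(frozen=True)
class PassProbability:
    """Monte-Carlo estimate of the probability that a simulated study passes."""

    n_replicates: int
    n_pass: int
    proportion: float
    ci_low: float
    ci_high: float  # 95% Wilson interval


def pass_probability(
    config: SimulationConfig,
    n_replicates: int,
    seed: int | None = None,
    quantities: Iterable[Quantity] = ("sbp", "dbp"),
    flank: FlankRule = "nearest",
) -> PassProbability:
    """Proportion of simulated cohorts whose overall (part-3) verdict is pass.

    By default "pass" means both blood-pressure quantities pass part 3; pass
    ``quantities=("sbp","dbp","hr")`` to require the heart-rate extension too.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    config.validate()
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    quantities = tuple(quantities)
    n_pass = 0
    for child in children:
        cohort = simulate_cohort(config, seed=child)
        if all(grade_cohort(cohort, q, flank).part3.passed for q in quantities):
            n_pass += 1
    lo, hi = proportion_confint(n_pass, n_replicates, alpha=0.05, method="wilson")
    p = n_pass / n_replicates
    return PassProbability(
        n_replicates=n_replicates,
        n_pass=n_pass,
        proportion=p,
        # guard against floating-point jitter at the boundaries
        ci_low=min(float(lo), p),
        ci_high=max(float(hi), p),
    )
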