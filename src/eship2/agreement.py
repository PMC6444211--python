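"""Agreement statistics: difference summaries, Bland-Altman limits, group comparisons.

The Bland-Altman analysis summarizes device-minus-reference differences by
their mean (bias) and the limits of agreement bias +/- 1.96 SD, plotted against
the per-pair means. The demographics comparison follows the normality-gated
scheme used in device-validation reports: Shapiro-Wilk on each group, then an
independent-samples Student t test if neither group rejects normality, else the
Wilcoxon-Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import Cohort, Quantity
from .pairing import ComparisonPair

__all__ = [
    "AgreementSummary",
    "summarize_differences",
    "GroupSummary",
    "GroupComparison",
    "compare_groups",
    "demographics_table",
]

LOA_MULTIPLIER = 1.96  # Bland-Altman convention for ~95% limits


@dataclass(frozen=True)
class AgreementSummary:
    quantity: Quantity
    n: int
    mean_signed: float
    sd_signed: float
    mean_absolute: float
    sd_absolute: float
    bias: float  # = mean_signed
    loa_lower: float
    loa_upper: float
    loa_multiplier: float
    points: tuple[tuple[float, float], ...]  # (pair mean, signed difference)


def summarize_differences(
    pairs: Sequence[ComparisonPair],
    loa_multiplier: float = LOA_MULTIPLIER,
) -> AgreementSummary:
    """Signed and absolute difference summaries plus Bland-Altman limits.

    SDs use the n-1 denominator. Requires at least two pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 comparison pairs to summarize")
    diffs = np.array([p.difference for p in pairs], dtype=float)
    means = np.array([p.pair_mean for p in pairs], dtype=float)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half_width = loa_multiplier * sd
    return AgreementSummary(
        quantity=pairs[0].quantity,
        n=len(pairs),
        mean_signed=bias,
        sd_signed=sd,
        mean_absolute=float(np.abs(diffs).mean()),
        sd_absolute=float(np.abs(diffs).std(ddof=1)),
        bias=bias,
        loa_lower=bias - half_width,
        loa_upper=bias + half_width,
        loa_multiplier=loa_multiplier,
        points=tuple(zip(means.tolist(), diffs.tolist())),
    )


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float


def _summarize_group(values: np.ndarray) -> GroupSummary:
    return GroupSummary(
        n=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        minimum=float(values.min()),
        maximum=float(values.max()),
    )


@dataclass(frozen=True)
class GroupComparison:
    test_used: str  # "t" or "rank-sum"
    statistic: float
    p_value: float
    group_a: GroupSummary
    group_b: GroupSummary
    shapiro_p: tuple[float, float] | None
    flags: tuple[str, ...] = ()


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group; if either rejects at ``alpha`` the
    Wilcoxon-Mann-Whitney rank-sum test is used, otherwise the independent
    two-sample Student t test (pooled variance by default; ``equal_var=False``
    gives Welch). A constant group makes the normality test inapplicable; the
    comparison then falls back to the rank-sum test and flags it.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")

    flags: list[str] = []
    shapiro_p: tuple[float, float] | None = None
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        flags.append("degenerate group (constant values); normality test inapplicable")
        use_t = False
    else:
        pa = float(stats.shapiro(a).pvalue)
        pb = float(stats.shapiro(b).pvalue)
        shapiro_p = (pa, pb)
        use_t = pa >= alpha and pb >= alpha

    if use_t:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test_used = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "rank-sum"
    p_value = float(res.pvalue)
    if math.isnan(p_value):  # e.g. both groups identical constants
        p_value = 1.0
        flags.append("p value undefined; reported as 1.0")
    return GroupComparison(
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=p_value,
        group_a=_summarize_group(a),
        group_b=_summarize_group(b),
        shapiro_p=shapiro_p,
        flags=tuple(flags),
    )


#: Characteristics compared between men and women in the demographics table.
DEMOGRAPHIC_CHARACTERISTICS = ("age", "weight", "height", "bmi", "arm_circumference")


def demographics_table(cohort: Cohort, alpha: float = 0.05) -> dict[str, GroupComparison]:
    """Men-vs-women comparison of each demographic characteristic.

    Returns an empty mapping when either sex has fewer than 3 members (the
    comparison is then undefined); this only happens on forced sub-standard
    cohorts.
    """
    men = [s.profile for s in cohort if s.profile.sex == "male"]
    women = [s.profile for s in cohort if s.profile.sex == "female"]
    if len(men) < 3 or len(women) < 3:
        return {}
    out = {}
    for name in DEMOGRAPHIC_CHARACTERISTICS:
        va = [getattr(p, name) for p in men]
        vb = [getattr(p, name) for p in women]
        out[name] = compare_groups(va, vb, alpha=alpha)
    return out
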