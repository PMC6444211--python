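"""Validation report assembly, serialization, and rendering.

:func:`run_validation` orchestrates the full pipeline — eligibility screening,
pairing, band classification, part-1/2/3 grading, agreement statistics and the
demographics table — into a single :class:`ValidationReport`. The report is a
pydantic model: it serializes to JSON, re-parses equal, and its JSON Schema is
shipped with the package (``eship2/schema/validation_report.schema.json``).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

from pydantic import BaseModel, Field

from . import agreement, grading, model, pairing
from .exceptions import EligibilityError
from .io import read_sessions_csv

__all__ = [
    "ValidationReport",
    "run_validation",
    "render_report",
    "parse_report",
    "report_json_schema",
    "load_shipped_schema",
]

log = logging.getLogger("eship2")

SCHEMA_VERSION = "1"
Mode = Literal["standard", "paper-literal"]


class CriterionModel(BaseModel):
    name: str
    achieved: int
    required: int
    kind: Literal["min", "max"]
    passed: bool


class VerdictModel(BaseModel):
    part: int
    passed: bool
    detail: list[CriterionModel]
    notes: list[str] = Field(default_factory=list)


class BandCountsModel(BaseModel):
    band_edges: tuple[float, float, float]
    counts: tuple[int, int, int]
    n_total: int


class RequirementModel(BaseModel):
    quantity_class: str
    band_edges: tuple[float, float, float]
    two_of_three: tuple[int, int, int]
    all_of_three: tuple[int, int, int]
    part2_min_with_2of3: int
    part2_max_with_0of3: int
    n_pairs: int
    n_participants: int
    scaled: bool


class AgreementModel(BaseModel):
    n: int
    mean_signed: float
    sd_signed: float
    mean_absolute: float
    sd_absolute: float
    bias: float
    loa_lower: float
    loa_upper: float
    loa_multiplier: float
    points: list[tuple[float, float]]


class QuantityReportModel(BaseModel):
    quantity: Literal["sbp", "dbp", "hr"]
    extension: bool  # True for HR: grading thresholds carried over from BP
    requirements: RequirementModel
    band_counts: BandCountsModel
    per_participant_band1: list[int]
    part1: VerdictModel
    part2: VerdictModel
    part3: VerdictModel
    agreement: AgreementModel
    literal_part1: VerdictModel | None = None
    mode_discrepancy: bool = False  # literal and standard part-1 verdicts differ


class EligibilityCheckModel(BaseModel):
    name: str
    passed: bool
    reason: str
    achieved: float
    required: float


class EligibilityModel(BaseModel):
    n_total: int
    n_male: int
    n_female: int
    eligible: bool
    checks: list[EligibilityCheckModel]
    warnings: list[str]


class GroupSummaryModel(BaseModel):
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float


class DemographicRowModel(BaseModel):
    characteristic: str
    men: GroupSummaryModel
    women: GroupSummaryModel
    test_used: str
    p_value: float
    flags: list[str] = Field(default_factory=list)


class ValidationReport(BaseModel):
    """Complete machine-readable outcome of one validation run."""

    schema_version: str = SCHEMA_VERSION
    device: dict[str, str] = Field(default_factory=dict)
    mode: Mode = "standard"
    flank: str = "nearest"
    n_participants: int
    standard_cohort_size: bool
    forced: bool = False
    eligibility: EligibilityModel
    quantities: dict[str, QuantityReportModel]
    demographics: list[DemographicRowModel]

    @property
    def all_passed(self) -> bool:
        return all(q.part3.passed for q in self.quantities.values())


def _verdict_model(v: grading.PartVerdict) -> VerdictModel:
    return VerdictModel(
        part=v.part, passed=v.passed,
        detail=[CriterionModel(**c.__dict__) for c in v.detail],
        notes=list(v.notes),
    )


def _literal_row(quantity: str) -> str:
    # the literal reading attaches the stricter printed row to SBP (and, by
    # analogy, HR) and the looser row to DBP
    return "all_of_three" if quantity == "dbp" else "two_of_three"


def _quantity_report(
    cohort: model.Cohort, quantity: model.Quantity, flank: str, mode: Mode
) -> QuantityReportModel:
    result = grading.grade_cohort(cohort, quantity, flank)
    pairs = pairing.cohort_comparisons(cohort, quantity, flank)
    summary = agreement.summarize_differences(pairs)
    literal = None
    discrepancy = False
    if mode == "paper-literal":
        literal_verdict = grading.part1_grade_literal(
            result.band_counts, result.table, _literal_row(quantity)
        )
        literal = _verdict_model(literal_verdict)
        discrepancy = literal_verdict.passed != result.part1.passed
    return QuantityReportModel(
        quantity=quantity,
        extension=(quantity == "hr"),
        requirements=RequirementModel(**result.table.__dict__),
        band_counts=BandCountsModel(**result.band_counts.__dict__),
        per_participant_band1=list(result.per_participant_band1),
        part1=_verdict_model(result.part1),
        part2=_verdict_model(result.part2),
        part3=_verdict_model(result.part3),
        agreement=AgreementModel(**{
            k: v for k, v in summary.__dict__.items() if k != "quantity"
        }),
        literal_part1=literal,
        mode_discrepancy=discrepancy,
    )


def run_validation(
    sessions: str | Path | model.Cohort,
    *,
    mode: Mode = "standard",
    flank: str = "nearest",
    quantities: tuple[model.Quantity, ...] = ("sbp", "dbp", "hr"),
    force: bool = False,
    device: Mapping[str, str] | None = None,
) -> ValidationReport:
    """Run the full validation pipeline on a session CSV or an in-memory cohort.

    Raises :class:`EligibilityError` if the cohort fails the recruitment
    requirements, unless ``force=True`` (the report then records ``forced``).
    """
    cohort = sessions if isinstance(sessions, model.Cohort) else read_sessions_csv(sessions)
    log.info("validating cohort of %d sessions (mode=%s, flank=%s)", len(cohort), mode, flank)

    elig = model.validate_cohort(cohort)
    if not elig.eligible and not force:
        raise EligibilityError(
            "cohort ineligible: " + "; ".join(elig.reasons) + " (use force to grade anyway)"
        )

    quantity_reports = {
        q: _quantity_report(cohort, q, flank, mode) for q in quantities
    }
    for q, rep in quantity_reports.items():
        log.info(
            "%s: bands %s of %d -> part1 %s, part2 %s, part3 %s",
            q, rep.band_counts.counts, rep.band_counts.n_total,
            rep.part1.passed, rep.part2.passed, rep.part3.passed,
        )

    demo = agreement.demographics_table(cohort)
    demographics = [
        DemographicRowModel(
            characteristic=name,
            men=GroupSummaryModel(**cmp.group_a.__dict__),
            women=GroupSummaryModel(**cmp.group_b.__dict__),
            test_used=cmp.test_used,
            p_value=cmp.p_value,
            flags=list(cmp.flags),
        )
        for name, cmp in demo.items()
    ]

    return ValidationReport(
        device=dict(device or {}),
        mode=mode,
        flank=flank,
        n_participants=len(cohort),
        standard_cohort_size=(len(cohort) == grading.STANDARD_N_PARTICIPANTS),
        forced=force and not elig.eligible,
        eligibility=EligibilityModel(
            n_total=elig.n_total, n_male=elig.n_male, n_female=elig.n_female,
            eligible=elig.eligible,
            checks=[EligibilityCheckModel(**c.__dict__) for c in elig.checks],
            warnings=list(elig.warnings),
        ),
        quantities=quantity_reports,
        demographics=demographics,
    )


def render_report(report: ValidationReport, format: str = "json") -> str:
    """Serialize a report as ``json`` (round-trips), ``text``, or ``markdown``."""
    if format == "json":
        return report.model_dump_json(indent=2)
    if format not in ("text", "markdown"):
        raise ValueError(f"unknown format {format!r}")

    md = format == "markdown"
    lines: list[str] = []
    h = (lambda s: f"## {s}") if md else (lambda s: s.upper())
    lines.append(("# " if md else "") + "Device validation report")
    if report.device:
        lines.append("device: " + ", ".join(f"{k}={v}" for k, v in report.device.items()))
    lines.append(
        f"mode: {report.mode}; flank rule: {report.flank}; "
        f"participants: {report.n_participants}"
        + ("" if report.standard_cohort_size else " (non-standard size, thresholds rescaled)")
    )
    lines.append("")
    lines.append(h("Eligibility"))
    e = report.eligibility
    lines.append(
        f"n={e.n_total} ({e.n_male} men, {e.n_female} women): "
        + ("eligible" if e.eligible else "INELIGIBLE" + (" (forced)" if report.forced else ""))
    )
    for c in e.checks:
        if not c.passed:
            lines.append(f"  failed: {c.reason} (achieved {c.achieved:g})")
    for w in e.warnings:
        lines.append(f"  warning: {w}")

    for q, rep in report.quantities.items():
        lines.append("")
        title = q.upper() + (" (heart-rate extension of the BP protocol)" if rep.extension else "")
        lines.append(h(title))
        req = rep.requirements
        if md:
            lines.append("| band | achieved | two-of-three row | all-of-three row |")
            lines.append("|---|---|---|---|")
        for edge, achieved, strict, loose in zip(
            req.band_edges, rep.band_counts.counts, req.two_of_three, req.all_of_three
        ):
            if md:
                lines.append(f"| <={edge:g} | {achieved} | {strict} | {loose} |")
            else:
                lines.append(
                    f"  within {edge:g}: achieved {achieved} of {rep.band_counts.n_total} "
                    f"(required {strict} two-of-three / {loose} all-of-three)"
                )
        for part, verdict in (("part 1", rep.part1), ("part 2", rep.part2), ("part 3", rep.part3)):
            lines.append(f"  {part}: {'PASS' if verdict.passed else 'FAIL'}")
            if part == "part 2":
                for c in verdict.detail:
                    op = ">=" if c.kind == "min" else "<="
                    lines.append(f"    {c.name}: {c.achieved} (required {op} {c.required})")
        if rep.literal_part1 is not None:
            lines.append(
                f"  part 1 (paper-literal single-row reading): "
                f"{'PASS' if rep.literal_part1.passed else 'FAIL'}"
                + ("  ** differs from standard semantics **" if rep.mode_discrepancy else "")
            )
        a = rep.agreement
        lines.append(
            f"  differences: signed {a.mean_signed:.2f} (SD {a.sd_signed:.2f}); "
            f"absolute {a.mean_absolute:.2f} (SD {a.sd_absolute:.2f}); "
            f"limits of agreement [{a.loa_lower:.2f}, {a.loa_upper:.2f}]"
        )

    lines.append("")
    lines.append(h("Demographics (men vs women)"))
    for row in report.demographics:
        lines.append(
            f"  {row.characteristic}: men {row.men.mean:.2f} (SD {row.men.sd:.2f}), "
            f"women {row.women.mean:.2f} (SD {row.women.sd:.2f}); "
            f"{row.test_used} test, p={row.p_value:.3f}"
        )
    lines.append("")
    overall = all(q.part3.passed for q in report.quantities.values())
    lines.append(("**" if md else "") + f"OVERALL: {'PASS' if overall else 'FAIL'}" + ("**" if md else ""))
    return "\n".join(lines)


def parse_report(text: str) -> ValidationReport:
    """Parse a JSON report back into a :class:`ValidationReport`."""
    return ValidationReport.model_validate_json(text)


def report_json_schema() -> dict:
    """The JSON Schema of :class:`ValidationReport` (as shipped with the package)."""
    return ValidationReport.model_json_schema()


def load_shipped_schema() -> dict:
    """Load the schema file distributed in ``eship2/schema/``."""
    with resources.files("eship2").joinpath(
        "schema/validation_report.schema.json"
    ).open("r", encoding="utf-8") as fh:
        return json.load(fh)
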