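"""Session CSV reading and writing.

One row per participant: demographic columns, three exclusion-flag columns,
then ``<slot>_sbp``, ``<slot>_dbp``, ``<slot>_hr`` for each of the nine slots
in schedule order. Header required, UTF-8, "." decimal separator. Integer and
fractional values are both accepted; values are stored as floats with no
rounding.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO

import pandas as pd

from .exceptions import CsvFormatError, ReadingError
from .model import (
    SLOT_ORDER,
    Cohort,
    ParticipantProfile,
    SessionRecord,
    TriplexReading,
    validate_session,
)

__all__ = ["SESSION_COLUMNS", "read_sessions_csv", "write_sessions_csv"]

log = logging.getLogger("eship2")

PROFILE_COLUMNS = (
    "id", "sex", "age", "weight_kg", "height_cm", "arm_circ_mm",
    "excluded_arrhythmia", "excluded_circulatory", "excluded_pregnant",
)
READING_COLUMNS = tuple(
    f"{slot}_{q}" for slot in SLOT_ORDER for q in ("sbp", "dbp", "hr")
)
SESSION_COLUMNS: tuple[str, ...] = PROFILE_COLUMNS + READING_COLUMNS

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(value, row_id: str, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CsvFormatError(f"row {row_id}: column {column}: cannot parse boolean {value!r}")


def _parse_sex(value, row_id: str) -> str:
    text = str(value).strip().lower()
    if text in ("male", "m"):
        return "male"
    if text in ("female", "f"):
        return "female"
    raise CsvFormatError(f"row {row_id}: column sex: expected male/female, got {value!r}")


def _parse_float(value, row_id: str, column: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise CsvFormatError(
            f"row {row_id}: column {column}: cannot parse number {value!r}"
        ) from None
    if pd.isna(out):
        raise CsvFormatError(f"row {row_id}: column {column}: missing value")
    return out


def read_sessions_csv(path: str | Path | IO[str]) -> Cohort:
    """Read a session CSV into a validated cohort.

    Raises :class:`CsvFormatError` naming the offending row/column on any
    malformed content, including missing columns and physically impossible
    readings.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CsvFormatError(f"cannot read session CSV: {exc}") from exc

    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise CsvFormatError(f"missing required columns: {', '.join(missing)}")

    sessions = []
    for idx, row in frame.iterrows():
        row_id = str(row["id"]).strip() or f"#{idx + 1}"
        profile = ParticipantProfile(
            id=row_id,
            sex=_parse_sex(row["sex"], row_id),
            age=_parse_float(row["age"], row_id, "age"),
            weight=_parse_float(row["weight_kg"], row_id, "weight_kg"),
            height=_parse_float(row["height_cm"], row_id, "height_cm"),
            arm_circumference=_parse_float(row["arm_circ_mm"], row_id, "arm_circ_mm"),
            excluded_arrhythmia=_parse_bool(row["excluded_arrhythmia"], row_id, "excluded_arrhythmia"),
            excluded_circulatory=_parse_bool(row["excluded_circulatory"], row_id, "excluded_circulatory"),
            excluded_pregnant=_parse_bool(row["excluded_pregnant"], row_id, "excluded_pregnant"),
        )
        readings = {}
        for slot in SLOT_ORDER:
            values = {
                q: _parse_float(row[f"{slot}_{q}"], row_id, f"{slot}_{q}")
                for q in ("sbp", "dbp", "hr")
            }
            try:
                readings[slot] = TriplexReading(**values)
            except ReadingError as exc:
                raise CsvFormatError(f"row {row_id}: slot {slot}: {exc}") from exc
        session = SessionRecord.from_readings(profile, readings)
        validate_session(session)
        sessions.append(session)
    log.info("read %d sessions from CSV", len(sessions))
    return Cohort(sessions)


def _fmt(x: float) -> str:
    # repr is the shortest exact representation: floats round-trip losslessly
    text = repr(float(x))
    return text[:-2] if text.endswith(".0") else text


def write_sessions_csv(cohort: Cohort, path: str | Path | IO[str]) -> None:
    """Write a cohort in the session CSV schema (round-trips value-identically)."""
    rows = []
    for s in cohort:
        p = s.profile
        row: dict[str, str] = {
            "id": p.id,
            "sex": p.sex,
            "age": _fmt(p.age),
            "weight_kg": _fmt(p.weight),
            "height_cm": _fmt(p.height),
            "arm_circ_mm": _fmt(p.arm_circumference),
            "excluded_arrhythmia": str(int(p.excluded_arrhythmia)),
            "excluded_circulatory": str(int(p.excluded_circulatory)),
            "excluded_pregnant": str(int(p.excluded_pregnant)),
        }
        for slot in SLOT_ORDER:
            r = s.readings[slot]
            row[f"{slot}_sbp"] = _fmt(r.sbp)
            row[f"{slot}_dbp"] = _fmt(r.dbp)
            row[f"{slot}_hr"] = _fmt(r.hr)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(SESSION_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")
    log.info("wrote %d sessions to CSV", len(rows))
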