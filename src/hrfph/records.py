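"""Patient-record CSV I/O.

One comma-separated row per patient (UTF-8, ``.`` decimal point, header
mandatory). The empty cell is the missing-value sentinel — never zero — and
``NA`` is accepted on read but never written. Unknown columns are preserved
verbatim and round-tripped. Per-row validation failures are collected with
their row numbers and raised together as :class:`~hrfph.errors.RecordParseError`
rather than silently dropping rows.

SpO2 readings are packed into one cell as ``value@SITE`` or
``value@SITE@offset_hours`` entries joined by ``;``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .composite import ScoreResult, VasoactiveDoses
from .config import DEFAULT_CONFIG, ScoreConfig
from .echo import EchoObservation
from .errors import RecordParseError, ScoringError, UnitError, ValidationError
from .oxygenation import OxygenationObservation, SpO2Reading, SpO2Site, SupportMode

__all__ = [
    "PatientRecord",
    "read_records",
    "write_records",
    "write_scored",
    "BOOL_OUTCOMES",
    "FLOAT_OUTCOMES",
]

OXY_COLS = (
    "mode",
    "flow_lpm",
    "fio2",
    "map_cmh2o",
    "pao2_mmhg",
    "gas_offset_hours",
    "spo2_readings",
)
ECHO_COLS = (
    "ivs_grade",
    "tapse_mm",
    "tr_velocity_ms",
    "rv_dysfunction",
    "systolic_bp_mmhg",
    "age_at_echo_days",
)
DOSE_COLS = (
    "dopamine",
    "dobutamine",
    "milrinone",
    "epinephrine",
    "norepinephrine",
    "vasopressin",
)
#: dichotomous outcome / covariate columns (1/0 in the file)
BOOL_OUTCOMES = (
    "died",
    "ecls",
    "death_or_ecls",
    "ino",
    "vasoactive",
    "imv",
    "hfov",
    "male",
    "meconium_aspiration",
    "lung_malformation",
)
#: continuous outcome columns
FLOAT_OUTCOMES = ("ino_hours", "imv_days", "los_days", "vis_max")

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


@dataclass
class PatientRecord:
    """A typed patient row; any component may be absent in a partial record."""

    patient_id: str
    oxygenation: OxygenationObservation | None = None
    echo: EchoObservation | None = None
    doses: VasoactiveDoses | None = None
    outcomes: dict[str, object] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _parse_float(cell: str, column: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"cannot parse {column}={cell!r} as a number") from None


def _parse_int(cell: str, column: str) -> int | None:
    value = _parse_float(cell, column)
    if value is None:
        return None
    if value != int(value):
        raise ValidationError(f"{column}={cell!r} must be an integer")
    return int(value)


def _parse_bool(cell: str, column: str) -> bool | None:
    if cell == "":
        return None
    low = cell.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"cannot parse {column}={cell!r} as a 0/1 flag")


def _parse_spo2(cell: str) -> tuple[SpO2Reading, ...]:
    if cell == "":
        return ()
    readings = []
    for chunk in cell.split(";"):
        parts = chunk.strip().split("@")
        if len(parts) not in (2, 3):
            raise ValidationError(
                f"SpO2 entry {chunk!r} must be value@SITE or value@SITE@offset_hours"
            )
        value = _parse_float(parts[0], "spo2")
        try:
            site = SpO2Site(parts[1].strip().upper())
        except ValueError:
            raise ValidationError(f"unknown SpO2 site {parts[1]!r}") from None
        offset = _parse_float(parts[2], "spo2 offset") if len(parts) == 3 else 0.0
        readings.append(SpO2Reading(value=value, site=site, offset_hours=offset or 0.0))
    return tuple(readings)


def _spo2_cell(readings: Sequence[SpO2Reading]) -> str:
    return ";".join(
        f"{_fmt(r.value)}@{r.site.value}"
        + (f"@{_fmt(r.offset_hours)}" if r.offset_hours else "")
        for r in readings
    )


def _row_to_record(row: dict[str, str], header: Sequence[str]) -> PatientRecord:
    get = lambda c: (row.get(c) or "").strip()
    norm = {c: ("" if get(c).upper() == "NA" else get(c)) for c in header}

    fio2_cell = norm.get("fio2", "")
    if fio2_cell:
        fio2 = _parse_float(fio2_cell, "fio2")
        if fio2 is not None and fio2 > 1.0:
            raise UnitError(
                f"fio2={fio2:g} is percent-scaled; use a fraction in [0.21, 1.0]"
            )

    oxy = None
    if norm.get("mode", ""):
        try:
            mode = SupportMode(norm["mode"].upper())
        except ValueError:
            raise ValidationError(f"unknown support mode {norm['mode']!r}") from None
        fio2 = _parse_float(norm.get("fio2", ""), "fio2")
        if fio2 is None:
            raise ValidationError("fio2 is required when a support mode is present")
        oxy = OxygenationObservation(
            mode=mode,
            fio2=fio2,
            flow_lpm=_parse_float(norm.get("flow_lpm", ""), "flow_lpm"),
            map_cmh2o=_parse_float(norm.get("map_cmh2o", ""), "map_cmh2o"),
            pao2_mmhg=_parse_float(norm.get("pao2_mmhg", ""), "pao2_mmhg"),
            gas_offset_hours=_parse_float(norm.get("gas_offset_hours", ""), "gas_offset_hours"),
            spo2_readings=_parse_spo2(norm.get("spo2_readings", "")),
        )

    echo = None
    if norm.get("ivs_grade", ""):
        rvd = _parse_bool(norm.get("rv_dysfunction", ""), "rv_dysfunction")
        sbp = _parse_float(norm.get("systolic_bp_mmhg", ""), "systolic_bp_mmhg")
        if sbp is None:
            raise ValidationError("systolic_bp_mmhg is required with echo fields")
        echo = EchoObservation(
            ivs_grade=_parse_int(norm["ivs_grade"], "ivs_grade"),
            tapse_mm=_parse_float(norm.get("tapse_mm", ""), "tapse_mm"),
            # empty cell = no measurable TR jet, a legal state
            tr_velocity_ms=_parse_float(norm.get("tr_velocity_ms", ""), "tr_velocity_ms"),
            rv_dysfunction=bool(rvd),
            systolic_bp_mmhg=sbp,
            age_at_echo_days=_parse_int(norm.get("age_at_echo_days", "")or "1", "age_at_echo_days"),
        )

    doses = None
    if any(norm.get(c, "") for c in DOSE_COLS):
        doses = VasoactiveDoses(
            **{c: _parse_float(norm.get(c, ""), c) or 0.0 for c in DOSE_COLS}
        )

    outcomes: dict[str, object] = {}
    for c in BOOL_OUTCOMES:
        if c in header:
            value = _parse_bool(norm.get(c, ""), c)
            if value is not None:
                outcomes[c] = value
    for c in FLOAT_OUTCOMES:
        if c in header:
            value = _parse_float(norm.get(c, ""), c)
            if value is not None:
                outcomes[c] = value

    known = {"patient_id", *OXY_COLS, *ECHO_COLS, *DOSE_COLS, *BOOL_OUTCOMES, *FLOAT_OUTCOMES}
    extra = {c: get(c) for c in header if c not in known}

    return PatientRecord(
        patient_id=norm.get("patient_id", ""),
        oxygenation=oxy,
        echo=echo,
        doses=doses,
        outcomes=outcomes,
        extra=extra,
    )


def read_records(path: str | Path, config: ScoreConfig = DEFAULT_CONFIG) -> list[PatientRecord]:
    """Read and validate a patient-record CSV; all bad rows reported at once."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing header with a patient_id column")
        header = list(reader.fieldnames)
        records: list[PatientRecord] = []
        errors: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                records.append(_row_to_record(row, header))
            except ScoringError as exc:
                errors.append((i, str(exc)))
    if errors:
        raise RecordParseError(errors)
    return records


def _record_to_row(rec: PatientRecord) -> dict[str, str]:
    row: dict[str, str] = {"patient_id": rec.patient_id}
    if rec.oxygenation is not None:
        o = rec.oxygenation
        row.update(
            mode=o.mode.value,
            flow_lpm=_fmt(o.flow_lpm),
            fio2=_fmt(o.fio2),
            map_cmh2o=_fmt(o.map_cmh2o),
            pao2_mmhg=_fmt(o.pao2_mmhg),
            gas_offset_hours=_fmt(o.gas_offset_hours),
            spo2_readings=_spo2_cell(o.spo2_readings),
        )
    if rec.echo is not None:
        e = rec.echo
        row.update(
            ivs_grade=_fmt(e.ivs_grade),
            tapse_mm=_fmt(e.tapse_mm),
            tr_velocity_ms=_fmt(e.tr_velocity_ms),
            rv_dysfunction=_fmt(e.rv_dysfunction),
            systolic_bp_mmhg=_fmt(e.systolic_bp_mmhg),
            age_at_echo_days=_fmt(e.age_at_echo_days),
        )
    if rec.doses is not None:
        row.update({c: _fmt(getattr(rec.doses, c)) for c in DOSE_COLS})
    for c, v in rec.outcomes.items():
        row[c] = _fmt(v)
    row.update(rec.extra)
    return row


def write_records(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as canonical CSV (column order fixed, extras appended)."""
    records = list(records)
    rows = [_record_to_row(r) for r in records]
    columns: list[str] = ["patient_id", *OXY_COLS, *ECHO_COLS]
    for block in (DOSE_COLS, BOOL_OUTCOMES, FLOAT_OUTCOMES):
        columns.extend(c for c in block if any(c in row for row in rows))
    seen = set(columns)
    for row in rows:
        for c in row:
            if c not in seen:
                seen.add(c)
                columns.append(c)
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=columns, restval="")
        writer.writeheader()
        writer.writerows(rows)


def write_scored(
    records: Sequence[PatientRecord],
    results: Sequence[ScoreResult],
    path: str | Path,
) -> None:
    """Write the per-patient scoring output table."""
    if len(records) != len(results):
        raise ValidationError("records and results must align one-to-one")
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "hrf", "ph", "total", "category"])
        for rec, res in zip(records, results):
            writer.writerow([rec.patient_id, res.hrf, res.ph, res.total, res.category.value])
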