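"""Oxygenation (hypoxemic-respiratory-failure) sub-score, 0-5.

The sub-score captures the level of respiratory support and oxygenation at
the time of the first echocardiogram. Infants on no support, nasal cannula or
high-flow nasal cannula score 0 or 1 (1 when flow >= 2 LPM or FiO2 >= 0.3).
Infants on CPAP, NIPPV, invasive ventilation or HFOV score 2-5 by band lookup
of a severity index: the oxygenation index

    OI = FiO2 * 100 * MAP / PaO2

when an arterial gas exists within the configured window (default 4 h) of the
echo, otherwise the non-invasive oxygen saturation index

    OSI = FiO2 * 100 * MAP / SpO2

computed from the preductal SpO2, preferring the right upper limb over the
left upper limb over a lower limb. MAP is mean airway pressure in cmH2O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .config import DEFAULT_CONFIG, AuditEntry, ScoreConfig
from .errors import DomainError, MissingDataError, UnitError, ValidationError

__all__ = [
    "SupportMode",
    "SpO2Site",
    "SpO2Reading",
    "OxygenationObservation",
    "IndexKind",
    "SeverityIndex",
    "HRFResult",
    "compute_oi",
    "compute_osi",
    "select_spo2",
    "select_severity_index",
    "oxygenation_score",
]


class SupportMode(str, Enum):
    """Respiratory support at echo time; HFOV scores like invasive ventilation."""

    NONE = "NONE"
    NASAL_CANNULA = "NASAL_CANNULA"
    HFNC = "HFNC"
    CPAP = "CPAP"
    NIPPV = "NIPPV"
    IMV = "IMV"
    HFOV = "HFOV"


#: modes scored 0/1 on the flow/FiO2 branch
LOW_FLOW_MODES = frozenset({SupportMode.NONE, SupportMode.NASAL_CANNULA, SupportMode.HFNC})
#: modes scored 2-5 on the OI/OSI branch (positive mean airway pressure required)
PRESSURE_MODES = frozenset({SupportMode.CPAP, SupportMode.NIPPV, SupportMode.IMV, SupportMode.HFOV})


class SpO2Site(str, Enum):
    RIGHT_UPPER_LIMB = "RIGHT_UPPER_LIMB"
    LEFT_UPPER_LIMB = "LEFT_UPPER_LIMB"
    LOWER_LIMB = "LOWER_LIMB"


_SITE_RANK = {
    SpO2Site.RIGHT_UPPER_LIMB: 0,
    SpO2Site.LEFT_UPPER_LIMB: 1,
    SpO2Site.LOWER_LIMB: 2,
}


@dataclass(frozen=True)
class SpO2Reading:
    """A pulse-oximetry reading; ``offset_hours`` is signed time from the echo."""

    value: float
    site: SpO2Site
    offset_hours: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 100.0:
            raise DomainError(f"SpO2 must be in (0, 100], got {self.value}")
        if not math.isfinite(self.offset_hours):
            raise DomainError("SpO2 offset_hours must be finite")


def _check_fio2(fio2: float) -> None:
    if fio2 > 1.0:
        raise UnitError(
            f"FiO2 = {fio2} looks percent-scaled; supply a fraction in [0.21, 1.0]"
        )
    if not 0.21 <= fio2 <= 1.0:
        raise ValidationError(f"FiO2 must be in [0.21, 1.0], got {fio2}")


@dataclass(frozen=True)
class OxygenationObservation:
    """Respiratory support and oxygenation state at the time of the echo."""

    mode: SupportMode
    fio2: float
    flow_lpm: float | None = None
    map_cmh2o: float | None = None
    pao2_mmhg: float | None = None
    gas_offset_hours: float | None = None
    spo2_readings: tuple[SpO2Reading, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_fio2(self.fio2)
        if self.flow_lpm is not None and self.flow_lpm < 0:
            raise ValidationError(f"flow_lpm must be >= 0, got {self.flow_lpm}")
        if self.map_cmh2o is not None and self.map_cmh2o < 0:
            raise ValidationError(f"map_cmh2o must be >= 0, got {self.map_cmh2o}")
        if self.mode in PRESSURE_MODES and not (self.map_cmh2o and self.map_cmh2o > 0):
            raise ValidationError(
                f"mode {self.mode.value} requires a positive mean airway pressure"
            )
        if self.pao2_mmhg is not None:
            if self.pao2_mmhg <= 0:
                raise DomainError(f"PaO2 must be > 0 mmHg, got {self.pao2_mmhg}")
            if self.gas_offset_hours is None:
                raise ValidationError("pao2_mmhg requires gas_offset_hours")
            if self.gas_offset_hours < 0:
                raise ValidationError("gas_offset_hours is |echo - gas| and must be >= 0")
        object.__setattr__(self, "spo2_readings", tuple(self.spo2_readings))


class IndexKind(str, Enum):
    OI = "OI"
    OSI = "OSI"


@dataclass(frozen=True)
class SeverityIndex:
    """Which oxygenation severity index was used, and its value."""

    kind: IndexKind
    value: float


@dataclass(frozen=True)
class HRFResult:
    points: int
    index: SeverityIndex | None
    audit: tuple[AuditEntry, ...]


def compute_oi(fio2: float, map_cmh2o: float, pao2_mmhg: float) -> float:
    """Oxygenation index, FiO2 * 100 * MAP / PaO2 (dimensionless)."""
    _check_fio2(fio2)
    if map_cmh2o < 0:
        raise ValidationError(f"mean airway pressure must be >= 0, got {map_cmh2o}")
    if pao2_mmhg <= 0:
        raise DomainError(f"PaO2 must be > 0 mmHg, got {pao2_mmhg}")
    return fio2 * 100.0 * map_cmh2o / pao2_mmhg


def compute_osi(fio2: float, map_cmh2o: float, spo2_pct: float) -> float:
    """Oxygen saturation index, FiO2 * 100 * MAP / SpO2 (dimensionless)."""
    _check_fio2(fio2)
    if map_cmh2o < 0:
        raise ValidationError(f"mean airway pressure must be >= 0, got {map_cmh2o}")
    if not 0.0 < spo2_pct <= 100.0:
        raise DomainError(f"SpO2 must be in (0, 100] percent, got {spo2_pct}")
    return fio2 * 100.0 * map_cmh2o / spo2_pct


def select_spo2(readings: Sequence[SpO2Reading]) -> SpO2Reading:
    """Pick the preductal reading: best site first, then nearest the echo.

    Site preference is right upper limb > left upper limb > lower limb. Among
    same-site readings the one closest in time to the echo wins; an exact
    time tie goes to the later reading so the choice stays deterministic.
    """
    readings = tuple(readings)
    if not readings:
        raise MissingDataError("no SpO2 readings available")
    return min(
        readings,
        key=lambda r: (_SITE_RANK[r.site], abs(r.offset_hours), -r.offset_hours),
    )


def select_severity_index(
    obs: OxygenationObservation, window_hours: float = 4.0
) -> SeverityIndex:
    """OI when a recent-enough arterial gas exists, else OSI from preductal SpO2."""
    if obs.map_cmh2o is None or obs.map_cmh2o <= 0:
        raise MissingDataError("OI/OSI need a positive mean airway pressure")
    if obs.pao2_mmhg is not None and obs.gas_offset_hours is not None:
        if obs.gas_offset_hours <= window_hours:
            return SeverityIndex(
                IndexKind.OI, compute_oi(obs.fio2, obs.map_cmh2o, obs.pao2_mmhg)
            )
    if obs.spo2_readings:
        reading = select_spo2(obs.spo2_readings)
        return SeverityIndex(
            IndexKind.OSI, compute_osi(obs.fio2, obs.map_cmh2o, reading.value)
        )
    raise MissingDataError(
        "neither an arterial gas within the window nor any SpO2 reading"
    )


def oxygenation_score(
    obs: OxygenationObservation, config: ScoreConfig = DEFAULT_CONFIG
) -> HRFResult:
    """Assign the 0-5 oxygenation sub-score with a band-lookup audit trail."""
    if obs.mode in LOW_FLOW_MODES:
        flow = obs.flow_lpm if obs.flow_lpm is not None else 0.0
        hit_flow = flow >= config.nc_flow_cutoff_lpm
        hit_fio2 = obs.fio2 >= config.nc_fio2_cutoff
        points = 1 if (hit_flow or hit_fio2) else 0
        band = (
            f"flow >= {config.nc_flow_cutoff_lpm:g} LPM or FiO2 >= "
            f"{config.nc_fio2_cutoff:g}"
        )
        audit = (
            AuditEntry(
                component=f"oxygenation:{obs.mode.value}",
                value=f"flow={flow:g} LPM, FiO2={obs.fio2:g}",
                band=band if points else f"not ({band})",
                grade=points,
            ),
        )
        return HRFResult(points=points, index=None, audit=audit)

    index = select_severity_index(obs, window_hours=config.gas_window_hours)
    bands = config.oi_bands if index.kind is IndexKind.OI else config.osi_bands
    grade, band = bands.lookup(index.value)
    audit = (
        AuditEntry(
            component=f"oxygenation:{index.kind.value}",
            value=index.value,
            band=band,
            grade=grade,
        ),
    )
    return HRFResult(points=grade, index=index, audit=audit)
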