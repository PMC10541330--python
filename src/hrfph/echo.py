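"""Echocardiographic (pulmonary-hypertension) sub-score, 0-10.

Four components from the first complete echocardiogram:

* IVS position grade 0-3 (parasternal short axis; 0 = normal bow into the RV,
  3 = bowing into the LV, i.e. suprasystemic pressures) — taken as the
  cardiologist's ordinal read, not computed from images.
* TAPSE grade 0-3 from the millimetre measurement (lower excursion = worse).
* RVsP grade 0-3 from the peak tricuspid-regurgitant jet velocity via the
  simplified Bernoulli equation RVsP = 4 v^2, graded relative to the systemic
  systolic blood pressure.
* RV dysfunction, present/absent, worth 1 point.

When no TR jet is measurable (no valve insufficiency) the RVsP cannot be
estimated; the IVS position score is then doubled, replacing the combined
IVS + RVsP contribution so the sub-score ceiling stays at 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import DEFAULT_CONFIG, AuditEntry, ScoreConfig
from .errors import DomainError, MissingDataError, ValidationError

__all__ = [
    "EchoObservation",
    "PHResult",
    "rvsp_from_tr",
    "grade_rvsp",
    "grade_tapse",
    "ph_score",
]


@dataclass(frozen=True)
class EchoObservation:
    """First-echo measurements feeding the PH sub-score.

    ``tr_velocity_ms is None`` means no measurable regurgitant jet — a legal
    state handled by the fallback, not an error. ``tapse_mm is None`` means
    TAPSE was not reported.
    """

    ivs_grade: int
    systolic_bp_mmhg: float
    rv_dysfunction: bool
    tapse_mm: float | None = None
    tr_velocity_ms: float | None = None
    age_at_echo_days: int = 1

    def __post_init__(self) -> None:
        if self.ivs_grade not in (0, 1, 2, 3):
            raise ValidationError(f"ivs_grade must be 0-3, got {self.ivs_grade}")
        if self.systolic_bp_mmhg <= 0:
            raise DomainError(
                f"systolic BP must be > 0 mmHg, got {self.systolic_bp_mmhg}"
            )
        if self.tapse_mm is not None and self.tapse_mm < 0:
            raise ValidationError(f"tapse_mm must be >= 0, got {self.tapse_mm}")
        if self.tr_velocity_ms is not None and self.tr_velocity_ms <= 0:
            raise DomainError(
                f"TR jet velocity must be > 0 m/s when present, got {self.tr_velocity_ms}"
            )
        if self.age_at_echo_days < 0:
            raise ValidationError("age_at_echo_days must be >= 0")


@dataclass(frozen=True)
class PHResult:
    points: int
    components: Mapping[str, int | None]
    fallback_used: bool
    audit: tuple[AuditEntry, ...]


def rvsp_from_tr(tr_velocity_ms: float) -> float:
    """Estimated RV systolic pressure (mmHg) by simplified Bernoulli, 4 v^2."""
    if tr_velocity_ms <= 0:
        raise DomainError(f"TR jet velocity must be > 0 m/s, got {tr_velocity_ms}")
    return 4.0 * tr_velocity_ms**2


def grade_rvsp(
    rvsp_mmhg: float, systolic_bp_mmhg: float, config: ScoreConfig = DEFAULT_CONFIG
) -> int:
    """Grade 0-3 of RVsP relative to systemic systolic pressure."""
    if rvsp_mmhg <= 0:
        raise DomainError(f"RVsP must be > 0 mmHg, got {rvsp_mmhg}")
    if systolic_bp_mmhg <= 0:
        raise DomainError(f"systolic BP must be > 0 mmHg, got {systolic_bp_mmhg}")
    grade, _ = config.rvsp_ratio_bands.lookup(rvsp_mmhg / systolic_bp_mmhg)
    return grade


def grade_tapse(tapse_mm: float, config: ScoreConfig = DEFAULT_CONFIG) -> int:
    """Grade 0-3 of TAPSE; lower excursion maps to a higher grade."""
    if tapse_mm < 0:
        raise ValidationError(f"tapse_mm must be >= 0, got {tapse_mm}")
    grade, _ = config.tapse_bands_mm.lookup(tapse_mm)
    return grade


def ph_score(echo: EchoObservation, config: ScoreConfig = DEFAULT_CONFIG) -> PHResult:
    """Assign the 0-10 echocardiographic sub-score with itemised components."""
    tapse_mm = echo.tapse_mm if echo.tapse_mm is not None else config.default_tapse_mm
    if tapse_mm is None:
        raise MissingDataError("TAPSE missing and no default_tapse_mm configured")
    tapse_g, tapse_band = config.tapse_bands_mm.lookup(tapse_mm)
    rvd = int(bool(echo.rv_dysfunction)) * config.rv_dysfunction_points

    audit: list[AuditEntry] = [
        AuditEntry("echo:IVS", echo.ivs_grade, "ordinal 0-3", echo.ivs_grade),
        AuditEntry("echo:TAPSE", tapse_mm, f"{tapse_band} mm", tapse_g),
        AuditEntry(
            "echo:RV_dysfunction",
            "present" if echo.rv_dysfunction else "absent",
            "present/absent",
            rvd,
        ),
    ]

    if echo.tr_velocity_ms is not None:
        rvsp = rvsp_from_tr(echo.tr_velocity_ms)
        ratio = rvsp / echo.systolic_bp_mmhg
        rvsp_g, ratio_band = config.rvsp_ratio_bands.lookup(ratio)
        audit.insert(
            2,
            AuditEntry("echo:RVsP/SBP", ratio, ratio_band, rvsp_g),
        )
        points = echo.ivs_grade + tapse_g + rvsp_g + rvd
        components: dict[str, int | None] = {
            "ivs": echo.ivs_grade,
            "tapse": tapse_g,
            "rvsp": rvsp_g,
            "rv_dysfunction": rvd,
            "ivs_doubled": None,
        }
        return PHResult(points, components, fallback_used=False, audit=tuple(audit))

    # no measurable TR jet: doubled IVS replaces the IVS + RVsP contribution
    doubled = 2 * echo.ivs_grade
    audit.insert(
        2,
        AuditEntry("echo:IVSx2(no TR jet)", echo.ivs_grade, "2 x IVS grade", doubled),
    )
    points = doubled + tapse_g + rvd
    components = {
        "ivs": echo.ivs_grade,
        "tapse": tapse_g,
        "rvsp": None,
        "rv_dysfunction": rvd,
        "ivs_doubled": doubled,
    }
    return PHResult(points, components, fallback_used=True, audit=tuple(audit))
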