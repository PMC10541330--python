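"""Composite HRF/PH score (0-15), severity category, and the VIS.

The oxygenation (0-5) and echocardiographic (0-10) sub-scores add to a total
of 0-15, categorised mild (0-5), moderate (6-10) or severe (11-15). The
vasoactive-inotropic score (VIS) is the standard weighted sum of infusion
doses and is configurable through :class:`~hrfph.config.VISCoefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .config import DEFAULT_CONFIG, AuditEntry, ScoreConfig
from .echo import EchoObservation, PHResult, ph_score
from .errors import ValidationError
from .oxygenation import HRFResult, OxygenationObservation, oxygenation_score

__all__ = [
    "Severity",
    "CATEGORY_ORDER",
    "ScoreResult",
    "VasoactiveDoses",
    "categorize",
    "total_score",
    "score_observation",
    "vis",
]


class Severity(str, Enum):
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


CATEGORY_ORDER: tuple[Severity, ...] = (Severity.MILD, Severity.MODERATE, Severity.SEVERE)


@dataclass(frozen=True)
class ScoreResult:
    """Total HRF/PH score with its decomposition and band-lookup audit trail."""

    hrf: int
    ph: int
    total: int
    category: Severity
    audit: tuple[AuditEntry, ...] = field(default_factory=tuple)


def categorize(total: int, config: ScoreConfig = DEFAULT_CONFIG) -> Severity:
    """Map a total score to its severity category (bounds inclusive as printed)."""
    bounds = config.categories
    if not isinstance(total, int) or isinstance(total, bool):
        raise ValidationError(f"total score must be an integer, got {total!r}")
    if not 0 <= total <= bounds.total_max:
        raise ValidationError(f"total score must be in [0, {bounds.total_max}], got {total}")
    if total <= bounds.mild_max:
        return Severity.MILD
    if total <= bounds.moderate_max:
        return Severity.MODERATE
    return Severity.SEVERE


def total_score(
    hrf: int,
    ph: int,
    config: ScoreConfig = DEFAULT_CONFIG,
    audit: tuple[AuditEntry, ...] = (),
) -> ScoreResult:
    """Combine the sub-scores; totals are integers so no rounding ever occurs."""
    if not isinstance(hrf, int) or not 0 <= hrf <= 5:
        raise ValidationError(f"oxygenation sub-score must be an integer in [0, 5], got {hrf}")
    if not isinstance(ph, int) or not 0 <= ph <= 10:
        raise ValidationError(f"echo sub-score must be an integer in [0, 10], got {ph}")
    total = hrf + ph
    return ScoreResult(hrf=hrf, ph=ph, total=total, category=categorize(total, config), audit=audit)


def score_observation(
    oxy: OxygenationObservation,
    echo: EchoObservation,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> ScoreResult:
    """Full pipeline: observations -> sub-scores -> total and category."""
    hrf: HRFResult = oxygenation_score(oxy, config)
    ph: PHResult = ph_score(echo, config)
    return total_score(hrf.points, ph.points, config, audit=hrf.audit + ph.audit)


@dataclass(frozen=True)
class VasoactiveDoses:
    """Infusion doses: catecholamines/milrinone in ug/kg/min, vasopressin in U/kg/min."""

    dopamine: float = 0.0
    dobutamine: float = 0.0
    milrinone: float = 0.0
    epinephrine: float = 0.0
    norepinephrine: float = 0.0
    vasopressin: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "dopamine",
            "dobutamine",
            "milrinone",
            "epinephrine",
            "norepinephrine",
            "vasopressin",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} dose must be >= 0")


def vis(doses: VasoactiveDoses, config: ScoreConfig = DEFAULT_CONFIG) -> float:
    """Vasoactive-inotropic score: weighted sum of the six infusion doses."""
    c = config.vis
    return (
        c.dopamine * doses.dopamine
        + c.dobutamine * doses.dobutamine
        + c.milrinone * doses.milrinone
        + c.epinephrine * doses.epinephrine
        + c.norepinephrine * doses.norepinephrine
        + c.vasopressin * doses.vasopressin
    )
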