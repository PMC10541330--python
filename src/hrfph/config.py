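"""Score configuration: every threshold and band table behind the HRF/PH score.

The published figure fixes the structure of the score (which components exist,
their grade ranges, the first oxygenation band) but not every interior cut
point, so all cut points live here, are serialisable to YAML, and can be
overridden without touching code. Band tables are lower-inclusive /
upper-exclusive and the top band is closed above, so together they tile
``[0, inf)`` with no gaps or overlaps by construction.

Default bands
-------------
* OI (oxygenation index): ``[0,10) -> 2, [10,15) -> 3, [15,25) -> 4,
  [25,inf) -> 5`` — anchored to the published first band (OI < 10 scores 2),
  increasing incrementally.
* OSI: the same grades at half the OI cut points (the usual OSI ~ OI/2
  relationship): ``5, 7.5, 12.5``.
* TAPSE (mm, lower is worse): ``[10,inf) -> 0, [8,10) -> 1, [6,8) -> 2,
  [0,6) -> 3`` — anchored to published term-neonate reference values.
* RVsP / systemic systolic BP ratio: ``[0,0.5) -> 0`` (sub-half-systemic),
  ``[0.5,2/3) -> 1``, ``[2/3,1) -> 2`` (near-systemic), ``[1,inf) -> 3``
  (systemic or suprasystemic).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError, DomainError

__all__ = [
    "AuditEntry",
    "BandTable",
    "CategoryBounds",
    "VISCoefficients",
    "ScoreConfig",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class AuditEntry:
    """One band-lookup decision recorded in a score's audit trail."""

    component: str
    value: float | str
    band: str
    grade: int


class BandTable(BaseModel):
    """Piecewise-constant lookup over ``[0, inf)``.

    ``cuts`` are the interior band edges in strictly increasing order; band
    ``i`` spans ``[cuts[i-1], cuts[i])`` (the first band starts at 0, the last
    is unbounded above) and maps to ``grades[i]``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    cuts: tuple[float, ...]
    grades: tuple[int, ...]

    @model_validator(mode="after")
    def _check(self) -> "BandTable":
        if len(self.grades) != len(self.cuts) + 1:
            raise ConfigError(
                f"need exactly len(cuts)+1 grades, got {len(self.grades)} "
                f"grades for {len(self.cuts)} cuts"
            )
        if any(c <= 0 or not math.isfinite(c) for c in self.cuts):
            raise ConfigError("band cuts must be finite and positive")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ConfigError("band cuts must be strictly increasing")
        diffs = [b - a for a, b in zip(self.grades, self.grades[1:])]
        if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ConfigError("grades must be strictly monotone across bands")
        return self

    def band_label(self, index: int) -> str:
        lo = 0.0 if index == 0 else self.cuts[index - 1]
        hi = self.cuts[index] if index < len(self.cuts) else math.inf
        return f"[{lo:g}, {hi:g})"

    def lookup(self, value: float) -> tuple[int, str]:
        """Return ``(grade, band_label)`` for ``value``.

        Bands are lower-inclusive, so a value sitting exactly on a cut belongs
        to the higher band.
        """
        if not math.isfinite(value) or value < 0:
            raise DomainError(f"band lookup requires a finite value >= 0, got {value}")
        i = bisect_right(self.cuts, value)
        return self.grades[i], self.band_label(i)

    def representative(self, grade: int) -> float:
        """A value guaranteed to fall in the (first) band carrying ``grade``.

        Finite bands return their midpoint; the unbounded top band returns
        1.25x its lower edge. Used by the synthetic-cohort generators.
        """
        for i, g in enumerate(self.grades):
            if g == grade:
                lo = 0.0 if i == 0 else self.cuts[i - 1]
                if i < len(self.cuts):
                    return (lo + self.cuts[i]) / 2.0
                return lo * 1.25 if lo > 0 else 1.0
        raise ConfigError(f"grade {grade} is not produced by this band table")

    def half_width(self, grade: int) -> float:
        """Half the width of the band carrying ``grade`` (top band: lo/4)."""
        for i, g in enumerate(self.grades):
            if g == grade:
                lo = 0.0 if i == 0 else self.cuts[i - 1]
                if i < len(self.cuts):
                    return (self.cuts[i] - lo) / 2.0
                return lo / 4.0 if lo > 0 else 1.0
        raise ConfigError(f"grade {grade} is not produced by this band table")


class CategoryBounds(BaseModel):
    """Severity category cut points on the 0-15 total."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    mild_max: int = 5
    moderate_max: int = 10
    total_max: int = 15

    @model_validator(mode="after")
    def _check(self) -> "CategoryBounds":
        if not (0 <= self.mild_max < self.moderate_max < self.total_max):
            raise ConfigError("category bounds must satisfy 0 <= mild < moderate < max")
        return self


class VISCoefficients(BaseModel):
    """Vasoactive-inotropic score weights (dose units in the field names).

    Standard formula: dopamine + dobutamine + 10*milrinone + 100*epinephrine
    + 100*norepinephrine + 10000*vasopressin, with catecholamines and
    milrinone in ug/kg/min and vasopressin in U/kg/min.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dopamine: float = 1.0
    dobutamine: float = 1.0
    milrinone: float = 10.0
    epinephrine: float = 100.0
    norepinephrine: float = 100.0
    vasopressin: float = 10000.0


class ScoreConfig(BaseModel):
    """Versioned, serialisable container for every tunable threshold."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    schema_version: int = 1
    # nasal-cannula / HFNC branch (oxygenation score 0 vs 1)
    nc_flow_cutoff_lpm: float = 2.0
    nc_fio2_cutoff: float = 0.30
    # arterial gas recency required to use OI instead of OSI
    gas_window_hours: float = 4.0
    oi_bands: BandTable = Field(
        default_factory=lambda: BandTable(cuts=(10.0, 15.0, 25.0), grades=(2, 3, 4, 5))
    )
    osi_bands: BandTable = Field(
        default_factory=lambda: BandTable(cuts=(5.0, 7.5, 12.5), grades=(2, 3, 4, 5))
    )
    tapse_bands_mm: BandTable = Field(
        default_factory=lambda: BandTable(cuts=(6.0, 8.0, 10.0), grades=(3, 2, 1, 0))
    )
    rvsp_ratio_bands: BandTable = Field(
        default_factory=lambda: BandTable(cuts=(0.5, 2.0 / 3.0, 1.0), grades=(0, 1, 2, 3))
    )
    rv_dysfunction_points: int = 1
    # optional imputation when TAPSE was not measured; None -> missing-data error
    default_tapse_mm: float | None = None
    vis: VISCoefficients = Field(default_factory=VISCoefficients)
    categories: CategoryBounds = Field(default_factory=CategoryBounds)

    @model_validator(mode="after")
    def _check(self) -> "ScoreConfig":
        if not 0.21 <= self.nc_fio2_cutoff <= 1.0:
            raise ConfigError("nc_fio2_cutoff must be an FiO2 fraction in [0.21, 1.0]")
        if self.nc_flow_cutoff_lpm <= 0 or self.gas_window_hours < 0:
            raise ConfigError("flow cutoff must be > 0 and gas window >= 0 hours")
        for name in ("oi_bands", "osi_bands"):
            if min(getattr(self, name).grades) < 2:
                raise ConfigError(f"{name} grades must start at 2 (pressure-support branch)")
        return self

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump(mode="json")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScoreConfig":
        try:
            return cls.model_validate(data)
        except ConfigError:
            raise
        except Exception as exc:  # pydantic ValidationError -> package error
            raise ConfigError(f"invalid score configuration: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)


DEFAULT_CONFIG = ScoreConfig()
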