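"""Synthetic cohorts: a deterministic printed-table fixture and a simulator.

Patient-level data behind the published cohort are not deposited, so this
module provides two substitutes:

* :func:`reconstruct_fixture` builds a deterministic 83-patient cohort whose
  category sizes and per-category outcome counts equal every printed
  marginal (category N 5/65/13; death-or-ECLS 0/12/10; ECLS 0/8/8; deaths
  0/7/7; iNO 1/50/13; vasoactive infusions 0/42/13; invasive ventilation
  1/49/13; HFOV 0/41/13; 53 males, 30 meconium aspirations, 5 lung
  malformations; 8 of the 14 deaths on ECLS). Each record carries raw
  physiologic measurements that score exactly to its assigned total, so the
  whole pipeline — not just the tabulation — is exercised. Within-category
  score values and continuous outcome values are reconstructions, not
  targets: only category-level quantities are published.

* :func:`simulate_cohort` draws stochastic cohorts with per-category raw
  input distributions and a monotone category -> outcome-probability link,
  for end-to-end property testing (category recovery, monotone event rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .composite import (
    CATEGORY_ORDER,
    Severity,
    VasoactiveDoses,
    categorize,
    score_observation,
)
from .config import DEFAULT_CONFIG, BandTable, ScoreConfig
from .echo import EchoObservation
from .errors import ConsistencyError, ValidationError
from .oxygenation import (
    OxygenationObservation,
    SpO2Reading,
    SpO2Site,
    SupportMode,
)
from .records import PatientRecord

__all__ = [
    "FixtureSpec",
    "SimulationParams",
    "SimulationResult",
    "decompose_total",
    "decompose_ph",
    "observation_for_scores",
    "reconstruct_fixture",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# score decomposition and raw-input synthesis
# ---------------------------------------------------------------------------


def decompose_total(total: int) -> tuple[int, int]:
    """Split a 0-15 total into a valid (oxygenation, echo) sub-score pair."""
    if not 0 <= total <= 15:
        raise ValidationError(f"total must be in [0, 15], got {total}")
    ph = min(10, (2 * total) // 3)
    hrf = total - ph
    if hrf > 5:
        ph += hrf - 5
        hrf = 5
    return hrf, ph


def decompose_ph(ph: int) -> tuple[int, int, int, int]:
    """Split a 0-10 echo sub-score into (ivs, tapse, rvsp, rv_dysfunction)."""
    if not 0 <= ph <= 10:
        raise ValidationError(f"ph must be in [0, 10], got {ph}")
    ivs = min(3, ph)
    rem = ph - ivs
    tapse = min(3, rem)
    rem -= tapse
    rvsp = min(3, rem)
    rvd = rem - rvsp
    return ivs, tapse, rvsp, rvd


# fio2 / MAP used on the pressure-support branch, indexed by oxygenation grade
_PRESSURE_SETTINGS = {2: (0.4, 10.0), 3: (0.6, 12.0), 4: (0.8, 14.0), 5: (1.0, 16.0)}
_FIXTURE_SBP = 65.0


def observation_for_scores(
    hrf: int, ph: int, config: ScoreConfig = DEFAULT_CONFIG
) -> tuple[OxygenationObservation, EchoObservation]:
    """Raw observations guaranteed to score exactly to ``(hrf, ph)``.

    Uses band midpoints from ``config``, so it stays correct under overridden
    band tables (as long as each grade is attainable).
    """
    if hrf == 0:
        oxy = OxygenationObservation(mode=SupportMode.NASAL_CANNULA, fio2=0.21, flow_lpm=0.5)
    elif hrf == 1:
        oxy = OxygenationObservation(mode=SupportMode.HFNC, fio2=0.4, flow_lpm=3.0)
    else:
        fio2, map_cmh2o = _PRESSURE_SETTINGS[hrf]
        oi = config.oi_bands.representative(hrf)
        pao2 = fio2 * 100.0 * map_cmh2o / oi
        oxy = OxygenationObservation(
            mode=SupportMode.IMV,
            fio2=fio2,
            map_cmh2o=map_cmh2o,
            pao2_mmhg=pao2,
            gas_offset_hours=1.0,
        )

    ivs, tapse_g, rvsp_g, rvd = decompose_ph(ph)
    tapse_mm = config.tapse_bands_mm.representative(tapse_g)
    ratio = config.rvsp_ratio_bands.representative(rvsp_g)
    if rvsp_g == 0:
        # bottom ratio band midpoint can be 0.25; keep a physiologic jet
        ratio = max(ratio, 0.2)
    velocity = math.sqrt(ratio * _FIXTURE_SBP / 4.0)
    echo = EchoObservation(
        ivs_grade=ivs,
        tapse_mm=tapse_mm,
        tr_velocity_ms=velocity,
        rv_dysfunction=bool(rvd),
        systolic_bp_mmhg=_FIXTURE_SBP,
        age_at_echo_days=1,
    )
    return oxy, echo


# ---------------------------------------------------------------------------
# fixture reconstruction
# ---------------------------------------------------------------------------

_CAT_KEYS = tuple(c.value for c in CATEGORY_ORDER)
Triple = tuple[int, int, int]


@dataclass(frozen=True)
class FixtureSpec:
    """Printed per-category marginals the fixture must reproduce exactly.

    Counts are (mild, moderate, severe) triples. ``continuous`` holds
    (q1, median, q3) display anchors per category for reconstructed —
    explicitly non-target — continuous outcomes.
    """

    category_sizes: Triple = (5, 65, 13)
    death_or_ecls: Triple = (0, 12, 10)
    ecls: Triple = (0, 8, 8)
    died: Triple = (0, 7, 7)
    ino: Triple = (1, 50, 13)
    vasoactive: Triple = (0, 42, 13)
    imv: Triple = (1, 49, 13)
    hfov: Triple = (0, 41, 13)
    male: Triple = (1, 43, 9)
    meconium_aspiration: Triple = (1, 25, 4)
    lung_malformation: Triple = (0, 2, 3)
    total_deaths_on_ecls: int = 8
    score_values: tuple[tuple[int, ...], ...] = (
        (2, 3, 4, 5, 5),
        tuple(6 + i % 5 for i in range(65)),
        tuple(11 + i % 2 for i in range(13)),
    )
    continuous: Mapping[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: {
            # reconstructed anchors, (q1, median, q3) per category
            "ino_hours": ((8.0, 8.0, 8.0), (57.0, 86.0, 158.0), (58.0, 120.0, 242.0)),
            "imv_days": ((1.0, 1.0, 1.0), (4.0, 6.5, 11.0), (4.0, 9.0, 16.0)),
            "los_days": ((13.0, 16.0, 23.0), (11.0, 19.0, 33.0), (16.0, 32.5, 76.0)),
            "vis_max": ((0.0, 0.0, 0.0), (9.0, 14.5, 27.5), (15.0, 25.0, 174.5)),
        }
    )

    def overlap_died_ecls(self, cat_index: int) -> int:
        """|died and ECLS| in a category, by inclusion-exclusion."""
        return self.died[cat_index] + self.ecls[cat_index] - self.death_or_ecls[cat_index]

    def validate(self) -> None:
        sizes = self.category_sizes
        if sum(sizes) != 83:
            raise ConsistencyError(f"category sizes must sum to 83, got {sum(sizes)}")
        for name in (
            "death_or_ecls", "ecls", "died", "ino", "vasoactive", "imv", "hfov",
            "male", "meconium_aspiration", "lung_malformation",
        ):
            triple = getattr(self, name)
            for i, (count, size) in enumerate(zip(triple, sizes)):
                if not 0 <= count <= size:
                    raise ConsistencyError(
                        f"{name}[{_CAT_KEYS[i]}] = {count} violates 0 <= count <= N = {size}"
                    )
        for i in range(3):
            ov = self.overlap_died_ecls(i)
            if ov < 0:
                raise ConsistencyError(
                    f"{_CAT_KEYS[i]}: died + ECLS - death_or_ecls = {ov} < 0 "
                    "(composite exceeds the union bound)"
                )
            if ov > min(self.died[i], self.ecls[i]):
                raise ConsistencyError(
                    f"{_CAT_KEYS[i]}: implied died-and-ECLS overlap {ov} exceeds "
                    f"min(died, ECLS) = {min(self.died[i], self.ecls[i])}"
                )
            if self.hfov[i] > self.imv[i]:
                raise ConsistencyError(
                    f"{_CAT_KEYS[i]}: HFOV count {self.hfov[i]} exceeds the "
                    f"ventilated count {self.imv[i]}"
                )
        if sum(self.overlap_died_ecls(i) for i in range(3)) != self.total_deaths_on_ecls:
            raise ConsistencyError(
                "per-category died-and-ECLS overlaps do not sum to total_deaths_on_ecls"
            )
        for i, (size, scores) in enumerate(zip(sizes, self.score_values)):
            if len(scores) != size:
                raise ConsistencyError(
                    f"{_CAT_KEYS[i]}: {len(scores)} score values for {size} patients"
                )
            for s in scores:
                if categorize(s) is not CATEGORY_ORDER[i]:
                    raise ConsistencyError(
                        f"score {s} assigned to the {_CAT_KEYS[i]} category"
                    )


def _quartile_ramp(m: int, anchors: tuple[float, float, float]) -> list[float]:
    """Deterministic values whose quartiles track (q1, median, q3)."""
    q1, med, q3 = anchors
    if m == 1:
        return [med]
    lo = q1 if q1 == med == q3 else max(q1 - (med - q1), 0.5 * q1)
    hi = q3 if q1 == med == q3 else q3 + (q3 - med)
    pos = np.linspace(0.0, 1.0, m)
    vals = np.interp(pos, [0.0, 0.25, 0.5, 0.75, 1.0], [lo, q1, med, q3, hi])
    return [round(float(v), 1) for v in vals]


def reconstruct_fixture(
    spec: FixtureSpec | None = None, config: ScoreConfig = DEFAULT_CONFIG
) -> list[PatientRecord]:
    """Build the deterministic 83-patient cohort satisfying every marginal.

    Within each category, ECLS goes to the first ``e`` records and deaths to
    records ``e - overlap .. e - overlap + d``, which realises the
    inclusion-exclusion overlap exactly; the other flags fill from the front.
    Continuous outcomes are assigned only where observed in the printed table
    (survivors, and users of the respective therapy).
    """
    spec = spec or FixtureSpec()
    spec.validate()

    records: list[PatientRecord] = []
    pid = 0
    for ci, cat in enumerate(CATEGORY_ORDER):
        size = spec.category_sizes[ci]
        scores = spec.score_values[ci]
        e, d = spec.ecls[ci], spec.died[ci]
        overlap = spec.overlap_died_ecls(ci)
        ecls_idx = set(range(e))
        died_idx = set(range(e - overlap, e - overlap + d))

        flags = {
            "ino": set(range(spec.ino[ci])),
            "vasoactive": set(range(spec.vasoactive[ci])),
            "imv": set(range(spec.imv[ci])),
            "hfov": set(range(spec.hfov[ci])),
            "male": set(range(spec.male[ci])),
            "meconium_aspiration": set(range(spec.meconium_aspiration[ci])),
            "lung_malformation": set(range(spec.lung_malformation[ci])),
        }

        # continuous values: deterministic quartile ramps over eligible records
        eligible = {
            "ino_hours": [i for i in range(size) if i in flags["ino"] and i not in died_idx],
            "imv_days": [i for i in range(size) if i in flags["imv"] and i not in died_idx],
            "los_days": [i for i in range(size) if i not in died_idx],
            "vis_max": [i for i in range(size) if i in flags["vasoactive"]],
        }
        values: dict[str, dict[int, float]] = {}
        for name, idx in eligible.items():
            if idx:
                values[name] = dict(zip(idx, _quartile_ramp(len(idx), spec.continuous[name][ci])))
            else:
                values[name] = {}

        for i in range(size):
            pid += 1
            total = scores[i]
            hrf, ph = decompose_total(total)
            oxy, echo = observation_for_scores(hrf, ph, config)
            outcomes: dict[str, object] = {
                "died": i in died_idx,
                "ecls": i in ecls_idx,
                "death_or_ecls": i in died_idx or i in ecls_idx,
            }
            for name, idx in flags.items():
                outcomes[name] = i in idx
            for name in ("ino_hours", "imv_days", "los_days", "vis_max"):
                if i in values[name]:
                    outcomes[name] = values[name][i]
            doses = None
            if i in flags["vasoactive"]:
                # dopamine-only dosing so that VIS equals the assigned maximum
                doses = VasoactiveDoses(dopamine=values["vis_max"].get(i, 10.0))
            records.append(
                PatientRecord(
                    patient_id=f"P{pid:03d}",
                    oxygenation=oxy,
                    echo=echo,
                    doses=doses,
                    outcomes=outcomes,
                    extra={"assigned_total": str(total), "assigned_category": cat.value},
                )
            )
    return records


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

# per-category event probabilities mirroring the printed outcome rates
_DEFAULT_OUTCOME_PROBS: dict[str, tuple[float, float, float]] = {
    "died": (0.0, 0.11, 0.54),
    "ecls": (0.0, 0.12, 0.62),
    "ino": (0.20, 0.77, 1.0),
    "vasoactive": (0.0, 0.65, 1.0),
    "imv": (0.20, 0.75, 1.0),
    "hfov": (0.0, 0.63, 1.0),
}
_DURATION_MEDIANS = {
    "ino_hours": (8.0, 86.0, 120.0),
    "imv_days": (1.0, 6.5, 9.0),
    "los_days": (16.0, 19.0, 32.5),
}


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the defaults emulate the printed cohort structure.

    ``band_noise`` is the standard deviation of each raw measurement around
    its band midpoint, as a fraction of the band half-width: 0.35 keeps
    roughly 99.6% of draws inside the intended band (well-separated
    categories). ``score_ranges`` are the per-category total-score supports.
    """

    seed: int
    n: int = 2000
    mixing: tuple[float, float, float] = (0.06, 0.78, 0.16)
    score_ranges: tuple[tuple[int, int], ...] = ((2, 5), (6, 10), (11, 12))
    band_noise: float = 0.35
    osi_prob: float = 0.30
    tr_absent_prob: float = 0.15
    sbp_mean: float = 65.0
    sbp_sd: float = 8.0
    male_prob: float = 0.64
    outcome_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_PROBS)
    )

    def validate(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if len(self.mixing) != 3 or any(p < 0 for p in self.mixing):
            raise ValidationError("mixing must be three non-negative proportions")
        if not math.isclose(sum(self.mixing), 1.0, abs_tol=1e-9):
            raise ValidationError(f"mixing proportions must sum to 1, got {sum(self.mixing)}")
        for name, probs in self.outcome_probs.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValidationError(f"outcome_probs[{name!r}] outside [0, 1]")
        for p in (self.osi_prob, self.tr_absent_prob, self.male_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for lo, hi in self.score_ranges:
            if not 0 <= lo <= hi <= 15:
                raise ValidationError(f"score range ({lo}, {hi}) outside [0, 15]")


@dataclass(frozen=True)
class SimulationResult:
    records: list[PatientRecord]
    recovery_rate: float
    per_category: dict[str, dict[str, int]]


def _jitter_in_band(bands: BandTable, grade: int, rng: np.random.Generator, noise: float) -> float:
    center = bands.representative(grade)
    sd = bands.half_width(grade) * noise
    return max(0.01, float(rng.normal(center, sd)))


def simulate_cohort(
    params: SimulationParams, config: ScoreConfig = DEFAULT_CONFIG
) -> SimulationResult:
    """Draw a reproducible cohort of raw records plus a recovery diagnostic.

    Each patient gets a generating category, a target total drawn from that
    category's score range, raw measurements jittered around the band
    midpoints realising that total, and outcomes drawn from the monotone
    per-category probabilities. ``recovery_rate`` is the fraction of records
    whose full-pipeline score lands back in the generating category.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    per_category = {
        c.value: {"generated": 0, "recovered": 0} for c in CATEGORY_ORDER
    }

    for i in range(params.n):
        ci = int(rng.choice(3, p=params.mixing))
        cat = CATEGORY_ORDER[ci]
        lo, hi = params.score_ranges[ci]
        total = int(rng.integers(lo, hi + 1))
        hrf, ph = decompose_total(total)

        # --- oxygenation ---------------------------------------------------
        if hrf == 0:
            oxy = OxygenationObservation(
                mode=SupportMode.NASAL_CANNULA,
                fio2=0.21,
                flow_lpm=float(rng.uniform(0.2, 1.5)),
            )
        elif hrf == 1:
            oxy = OxygenationObservation(
                mode=SupportMode.HFNC,
                fio2=round(float(rng.uniform(0.30, 0.60)), 2),
                flow_lpm=float(rng.uniform(2.5, 6.0)),
            )
        else:
            mode = SupportMode.HFOV if rng.random() < 0.3 else SupportMode.IMV
            fio2, map_ref = _PRESSURE_SETTINGS[hrf]
            if rng.random() < params.osi_prob:
                osi = _jitter_in_band(config.osi_bands, hrf, rng, params.band_noise)
                spo2 = round(float(rng.uniform(85.0, 97.0)), 1)
                map_cmh2o = osi * spo2 / (100.0 * fio2)
                oxy = OxygenationObservation(
                    mode=mode,
                    fio2=fio2,
                    map_cmh2o=map_cmh2o,
                    spo2_readings=(
                        SpO2Reading(value=spo2, site=SpO2Site.RIGHT_UPPER_LIMB),
                    ),
                )
            else:
                oi = _jitter_in_band(config.oi_bands, hrf, rng, params.band_noise)
                pao2 = fio2 * 100.0 * map_ref / oi
                oxy = OxygenationObservation(
                    mode=mode,
                    fio2=fio2,
                    map_cmh2o=map_ref,
                    pao2_mmhg=pao2,
                    gas_offset_hours=float(rng.uniform(0.0, 3.5)),
                )

        # --- echocardiogram ------------------------------------------------
        ivs, tapse_g, rvsp_g, rvd = decompose_ph(ph)
        tapse_mm = _jitter_in_band(config.tapse_bands_mm, tapse_g, rng, params.band_noise)
        sbp = max(35.0, float(rng.normal(params.sbp_mean, params.sbp_sd)))
        tr_absent = rvsp_g == ivs and rng.random() < params.tr_absent_prob
        if tr_absent:
            velocity = None
        else:
            ratio = _jitter_in_band(config.rvsp_ratio_bands, rvsp_g, rng, params.band_noise)
            velocity = math.sqrt(max(ratio, 0.05) * sbp / 4.0)
        echo = EchoObservation(
            ivs_grade=ivs,
            tapse_mm=tapse_mm,
            tr_velocity_ms=velocity,
            rv_dysfunction=bool(rvd),
            systolic_bp_mmhg=sbp,
            age_at_echo_days=int(rng.integers(0, 4)),
        )

        # --- outcomes (monotone in category) -------------------------------
        outcomes: dict[str, object] = {}
        for name, probs in params.outcome_probs.items():
            outcomes[name] = bool(rng.random() < probs[ci])
        outcomes["death_or_ecls"] = bool(outcomes.get("died")) or bool(outcomes.get("ecls"))
        outcomes["male"] = bool(rng.random() < params.male_prob)
        if not outcomes.get("died"):
            for name, med in _DURATION_MEDIANS.items():
                gate = {"ino_hours": "ino", "imv_days": "imv", "los_days": None}[name]
                if gate is None or outcomes.get(gate):
                    outcomes[name] = round(
                        float(rng.lognormal(math.log(med[ci]), 0.6)), 1
                    )
        doses = None
        if outcomes.get("vasoactive"):
            doses = VasoactiveDoses(dopamine=round(float(rng.uniform(5.0, 20.0)), 1))

        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:05d}",
                oxygenation=oxy,
                echo=echo,
                doses=doses,
                outcomes=outcomes,
                extra={"sim_category": cat.value, "sim_total": str(total)},
            )
        )
        per_category[cat.value]["generated"] += 1

    recovered = 0
    for rec in records:
        result = score_observation(rec.oxygenation, rec.echo, config)
        if result.category.value == rec.extra["sim_category"]:
            recovered += 1
            per_category[rec.extra["sim_category"]]["recovered"] += 1
    return SimulationResult(
        records=records,
        recovery_rate=recovered / len(records),
        per_category=per_category,
    )
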