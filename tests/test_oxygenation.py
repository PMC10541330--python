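"""Oxygenation sub-score: OI/OSI formulas, SpO2 selection, branch logic."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrfph import (
    DomainError,
    IndexKind,
    MissingDataError,
    OxygenationObservation,
    SpO2Reading,
    SpO2Site,
    SupportMode,
    UnitError,
    ValidationError,
    compute_oi,
    compute_osi,
    oxygenation_score,
    select_severity_index,
    select_spo2,
)

RUL, LUL, LL = SpO2Site.RIGHT_UPPER_LIMB, SpO2Site.LEFT_UPPER_LIMB, SpO2Site.LOWER_LIMB


@pytest.mark.parametrize(
    "fio2, map_, pao2, expected",
    [(1.0, 20, 40, 50.0), (0.5, 10, 50, 10.0), (0.21, 0, 60, 0.0)],
)
def test_oi_formula(fio2, map_, pao2, expected):
    assert compute_oi(fio2, map_, pao2) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "fio2, map_, spo2, expected", [(1.0, 20, 80, 25.0), (0.4, 10, 100, 4.0)]
)
def test_osi_formula(fio2, map_, spo2, expected):
    assert compute_osi(fio2, map_, spo2) == pytest.approx(expected, abs=1e-12)


@given(
    fio2=st.floats(0.21, 1.0),
    map_=st.floats(0.0, 30.0),
    x=st.floats(10.0, 100.0),
)
@settings(derandomize=True, max_examples=200)
def test_osi_equals_oi_when_saturation_matches_pao2(fio2, map_, x):
    assert compute_osi(fio2, map_, x) == compute_oi(fio2, map_, x)


def test_oi_rejects_nonpositive_pao2():
    with pytest.raises(DomainError):
        compute_oi(0.5, 10, 0)


def test_percent_scale_fio2_is_a_unit_error():
    with pytest.raises(UnitError):
        compute_oi(40, 10, 50)
    with pytest.raises(ValidationError):
        compute_oi(0.1, 10, 50)


class TestSelectSpO2:
    def test_site_preference_order(self):
        picked = select_spo2([SpO2Reading(97, LL), SpO2Reading(92, RUL)])
        assert picked.value == 92 and picked.site is RUL
        picked = select_spo2([SpO2Reading(90, LUL), SpO2Reading(88, LL)])
        assert picked.value == 90 and picked.site is LUL

    def test_singleton(self):
        assert select_spo2([SpO2Reading(95, LUL)]).value == 95

    def test_same_site_nearest_echo_wins(self):
        picked = select_spo2(
            [SpO2Reading(90, RUL, offset_hours=-2.0), SpO2Reading(88, RUL, offset_hours=0.5)]
        )
        assert picked.value == 88

    def test_equidistant_tie_goes_to_later_reading(self):
        picked = select_spo2(
            [SpO2Reading(90, RUL, offset_hours=-1.0), SpO2Reading(88, RUL, offset_hours=1.0)]
        )
        assert picked.offset_hours == 1.0

    def test_empty_list_is_missing_data(self):
        with pytest.raises(MissingDataError):
            select_spo2([])


class TestSeverityIndexSelection:
    def test_recent_gas_uses_oi(self):
        obs = OxygenationObservation(
            mode=SupportMode.IMV, fio2=1.0, map_cmh2o=20, pao2_mmhg=40, gas_offset_hours=2
        )
        idx = select_severity_index(obs)
        assert idx.kind is IndexKind.OI and idx.value == pytest.approx(50.0)

    def test_stale_gas_falls_back_to_osi(self):
        obs = OxygenationObservation(
            mode=SupportMode.IMV,
            fio2=1.0,
            map_cmh2o=20,
            pao2_mmhg=40,
            gas_offset_hours=6,
            spo2_readings=(SpO2Reading(80, RUL),),
        )
        idx = select_severity_index(obs)
        assert idx.kind is IndexKind.OSI and idx.value == pytest.approx(25.0)

    def test_no_gas_uses_osi(self):
        obs = OxygenationObservation(
            mode=SupportMode.CPAP,
            fio2=0.4,
            map_cmh2o=10,
            spo2_readings=(SpO2Reading(100, RUL),),
        )
        idx = select_severity_index(obs)
        assert idx.kind is IndexKind.OSI and idx.value == pytest.approx(4.0)

    def test_nothing_usable_is_missing_data(self):
        obs = OxygenationObservation(mode=SupportMode.IMV, fio2=0.4, map_cmh2o=10)
        with pytest.raises(MissingDataError):
            select_severity_index(obs)


class TestOxygenationScore:
    @pytest.mark.parametrize(
        "mode, flow, fio2, expected",
        [
            (SupportMode.NASAL_CANNULA, 1.0, 0.21, 0),
            (SupportMode.HFNC, 2.0, 0.21, 1),  # flow threshold
            (SupportMode.NASAL_CANNULA, 0.5, 0.30, 1),  # FiO2 threshold
            (SupportMode.NONE, None, 0.21, 0),
        ],
    )
    def test_low_flow_branch(self, mode, flow, fio2, expected, config):
        obs = OxygenationObservation(mode=mode, fio2=fio2, flow_lpm=flow)
        assert oxygenation_score(obs, config).points == expected

    def test_oi_band_boundary_is_lower_inclusive(self, config):
        # OI exactly 10 belongs to the [10, 15) band -> 3
        obs = OxygenationObservation(
            mode=SupportMode.IMV, fio2=0.5, map_cmh2o=10, pao2_mmhg=50, gas_offset_hours=1
        )
        result = oxygenation_score(obs, config)
        assert result.index.value == pytest.approx(10.0)
        assert result.points == 3
        assert result.audit[0].band == "[10, 15)"

    def test_invasive_mode_requires_map(self):
        with pytest.raises(ValidationError):
            OxygenationObservation(mode=SupportMode.IMV, fio2=0.5)

    def test_hfov_scores_on_invasive_branch(self, config):
        obs = OxygenationObservation(
            mode=SupportMode.HFOV, fio2=0.5, map_cmh2o=10, pao2_mmhg=200, gas_offset_hours=1
        )
        assert oxygenation_score(obs, config).points >= 2

    @given(pao2=st.floats(10.0, 400.0))
    @settings(derandomize=True, max_examples=100)
    def test_range_and_branch_floors(self, pao2, config):
        obs = OxygenationObservation(
            mode=SupportMode.IMV, fio2=0.8, map_cmh2o=14, pao2_mmhg=pao2, gas_offset_hours=1
        )
        points = oxygenation_score(obs, config).points
        assert 2 <= points <= 5

    @given(oi_pair=st.tuples(st.floats(0.0, 60.0), st.floats(0.0, 60.0)))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_severity_index(self, oi_pair, config):
        def score_at(oi):
            if oi == 0:
                return 2  # OI 0 sits in the bottom invasive band
            obs = OxygenationObservation(
                mode=SupportMode.IMV,
                fio2=1.0,
                map_cmh2o=10,
                pao2_mmhg=1000.0 / oi,
                gas_offset_hours=1,
            )
            return oxygenation_score(obs, config).points

        lo, hi = sorted(oi_pair)
        assert score_at(lo) <= score_at(hi)

    def test_determinism(self, config):
        obs = OxygenationObservation(
            mode=SupportMode.IMV, fio2=0.6, map_cmh2o=12, pao2_mmhg=55, gas_offset_hours=2
        )
        a, b = oxygenation_score(obs, config), oxygenation_score(obs, config)
        assert a == b
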