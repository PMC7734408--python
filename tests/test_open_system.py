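import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoanammox.open_system import (
    ReactorState,
    apparent_amx_15,
    apparent_amxnir_15,
    apparent_amxnir_15_raw,
    apparent_combined_18,
    apparent_nxr_15,
    d15_n2_back_calculated,
    fraction_reacted,
    mixing_coefficients,
    plant_effects,
    stoichiometric_ratios,
)
from isoanammox.synthetic_data import generate_plant_train


def make_pair(**kw):
    nt = ReactorState("NT", nh4=18.7, no2=21.2, no3=0.0, d15_nh4=19.2, d15_no2=-28.2)
    anx = ReactorState(
        "ANX", nh4=1.9, no2=0.4, no3=2.5, d15_nh4=50.2, d15_no2=-21.6,
        d18_no2=3.3, d15_no3=9.3, d18_no3=2.7,
    )
    return nt, anx


class TestFractionReacted:
    def test_plant_value(self, nt_anx):
        assert fraction_reacted(*nt_anx) == pytest.approx((18.7 - 1.9) / 18.7)

    def test_no_consumption(self):
        r = ReactorState("r", nh4=5.0)
        assert fraction_reacted(r, r) == 0.0

    def test_complete_consumption(self):
        assert fraction_reacted(ReactorState("a", nh4=5.0), ReactorState("b")) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            fraction_reacted(ReactorState("a", nh4=0.0), ReactorState("b"))
        with pytest.raises(ValueError):
            fraction_reacted(ReactorState("a", nh4=1.0), ReactorState("b", nh4=2.0))


class TestApparentEffects:
    def test_amx_plant_band(self, nt_anx):
        val = apparent_amx_15(*nt_anx)
        assert val == pytest.approx(34.5, abs=0.1)

    def test_amx_offset_invariance(self, nt_anx):
        nt, anx = nt_anx
        nt2 = ReactorState("NT", nh4=nt.nh4, d15_nh4=nt.d15_nh4 + 100.0)
        anx2 = ReactorState("ANX", nh4=anx.nh4, d15_nh4=anx.d15_nh4 + 100.0)
        assert apparent_amx_15(nt2, anx2) == pytest.approx(apparent_amx_15(nt, anx))

    def test_amx_linear_form(self):
        nt = ReactorState("NT", nh4=2.0, d15_nh4=0.0)
        anx = ReactorState("ANX", nh4=1.0, d15_nh4=10.0)
        assert apparent_amx_15(nt, anx) == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "d15_no2, d15_no3, expected", [(-21.6, 9.3, -30.9), (4.0, 4.0, 0.0), (0.0, -5.0, 5.0)]
    )
    def test_nxr(self, d15_no2, d15_no3, expected):
        anx = ReactorState("ANX", d15_no2=d15_no2, d15_no3=d15_no3)
        assert apparent_nxr_15(anx) == pytest.approx(expected)

    def test_nxr_missing_delta(self):
        with pytest.raises(ValueError, match="missing"):
            apparent_nxr_15(ReactorState("ANX", d15_no2=1.0))

    def test_mixing_coefficients_plant(self, nt_anx):
        a, b = mixing_coefficients(*nt_anx)
        assert a == pytest.approx(0.4 / 20.8)
        assert b == pytest.approx(2.5 / 20.8)

    def test_mixing_coefficients_trivial(self):
        nt = ReactorState("NT", no2=5.0)
        anx = ReactorState("ANX", no2=0.0, no3=0.0)
        assert mixing_coefficients(nt, anx) == (0.0, 0.0)

    def test_mixing_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mixing_coefficients(ReactorState("NT", no2=1.0), ReactorState("ANX", no2=1.0))

    def test_amxnir_plant_sign_convention(self, nt_anx):
        # the raw steady-state quotient is negative on the plant data; the
        # reported substrate-minus-product value is its positive mirror and
        # must agree with the back-calculated N2 delta
        nt, anx = nt_anx
        raw = apparent_amxnir_15_raw(nt, anx)
        val = apparent_amxnir_15(nt, anx)
        assert raw < 0 < val
        assert val == pytest.approx(-raw)
        d15_n2 = d15_n2_back_calculated(nt, anx)
        assert val == pytest.approx(anx.d15_no2 - d15_n2, abs=1e-9)
        assert val == pytest.approx(12.0, abs=0.2)

    def test_amxnir_zero_when_flat(self):
        nt = ReactorState("NT", no2=5.0, d15_no2=3.0)
        anx = ReactorState("ANX", no2=1.0, no3=0.0, d15_no2=3.0, d15_no3=0.0)
        assert apparent_amxnir_15(nt, anx) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "d18_no2, d18_no3, water, expected",
        [(3.3, 2.7, -8.0, 2.2 - 8.0 / 3.0 - 2.7), (5.0, 5.0, 5.0, 0.0), (0.0, -9.0, 0.0, 9.0)],
    )
    def test_combined_18(self, d18_no2, d18_no3, water, expected):
        anx = ReactorState("ANX", d18_no2=d18_no2, d18_no3=d18_no3)
        assert apparent_combined_18(anx, water) == pytest.approx(expected)


class TestStoichiometry:
    def test_plant_ratios_in_anammox_range(self, nt_anx):
        r_no2, r_no3 = stoichiometric_ratios(*nt_anx)
        assert 1.03 <= r_no2 <= 1.32
        assert 0.14 <= r_no3 <= 0.35


class TestInversion:
    @given(
        d15_amx=st.floats(5.0, 50.0),
        d15_nxr=st.floats(-90.0, -5.0),
        d15_amxnir=st.floats(1.0, 30.0),
        e18=st.floats(-15.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_forward_construct_then_invert(self, d15_amx, d15_nxr, d15_amxnir, e18):
        nt, anx = generate_plant_train(d15_amx, d15_nxr, d15_amxnir, e18)
        eff = plant_effects(nt, anx, d18_water=-8.0)
        assert eff.d15_amx == pytest.approx(d15_amx, abs=1e-9)
        assert eff.d15_nxr == pytest.approx(d15_nxr, abs=1e-9)
        assert eff.d15_amxnir == pytest.approx(d15_amxnir, abs=1e-9)
        assert eff.e18_combined == pytest.approx(e18, abs=1e-9)

    def test_target_16_permil_recovered(self):
        nt, anx = generate_plant_train(30.0, -30.0, 16.0, -3.0)
        assert apparent_amxnir_15(nt, anx) == pytest.approx(16.0, abs=1e-9)

    def test_all_zero_effects_flat_train(self):
        nt, anx = generate_plant_train(0.0, 0.0, 0.0, 0.0, d18_no2_anx=0.0,
                                       d18_water=0.0, d15_nh4_nt=0.0, d15_no2_anx=0.0)
        assert anx.d15_nh4 == pytest.approx(nt.d15_nh4)
        assert anx.d15_no3 == pytest.approx(anx.d15_no2)
        assert nt.d15_no2 == pytest.approx(anx.d15_no2)
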