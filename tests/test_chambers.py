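"""Constitutive laws: polynomial curves, twitch, Laplace geometry."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from windkessel.chambers import (
    AtriumParameters,
    VentricleParameters,
    area_factor,
    atrial_activation,
    ejection_derating,
    isovolumic_max_pressure,
    la_pressure,
    lv_activation,
    lv_pressure,
    lv_wall_stress,
    passive_lv_pressure,
)

VENT = VentricleParameters()
ATR = AtriumParameters()


class TestPassivePressure:
    @pytest.mark.parametrize(
        "V, P_Ved_M, expected",
        [
            (0.0, 40.0, 0.0),  # cubic through the origin
            (200.0, 40.0, 40.0),  # anchor point of the end-diastolic curve
            (114.0, 40.0, 40.0 * (114.0 / 200.0) ** 3),
        ],
    )
    def test_values(self, V, P_Ved_M, expected):
        p = VentricleParameters(P_Ved_M=P_Ved_M)
        assert passive_lv_pressure(V, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            passive_lv_pressure(-1.0, VENT)

    @given(st.floats(1.0, 300.0), st.floats(1.0, 300.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_increasing(self, v1, v2):
        lo, hi = sorted((v1, v2))
        assert passive_lv_pressure(lo, VENT) <= passive_lv_pressure(hi, VENT)


class TestIsovolumicMaximum:
    def test_peak_is_275_at_200_ml(self):
        assert isovolumic_max_pressure(200.0, VENT) == pytest.approx(275.0)

    def test_zero_volume_gives_zero(self):
        # 275 - (275/200^2) * 200^2 = 0 by construction of b_V
        assert isovolumic_max_pressure(0.0, VENT) == pytest.approx(0.0, abs=1e-10)

    def test_intermediate_volume(self):
        assert isovolumic_max_pressure(114.0, VENT) == pytest.approx(
            275.0 - (275.0 / 200.0**2) * 86.0**2, rel=1e-12
        )

    @given(st.floats(0.0, 199.0))
    @settings(derandomize=True, max_examples=50)
    def test_maximum_attained_at_anchor(self, v):
        assert isovolumic_max_pressure(v, VENT) < isovolumic_max_pressure(200.0, VENT)


class TestAreaFactor:
    def test_ratio_seven_gives_three(self):
        # (7+1)^(1/3)-1 = 1, so A_V = 2+1 = 3
        assert area_factor(7.0, 1.0) == pytest.approx(3.0, rel=1e-12)

    def test_membrane_limit(self):
        assert area_factor(1e-9, 100.0) == pytest.approx(0.0, abs=1e-9)

    def test_zero_cavity_rejected(self):
        with pytest.raises(ValueError):
            area_factor(150.0, 0.0)

    @given(st.floats(5.0, 60.0), st.floats(1.0, 40.0))
    @settings(derandomize=True, max_examples=100)
    def test_geometric_round_trip(self, r, h):
        """Building V_V and V_m from sphere radii reproduces 2(h/r)+(h/r)^2."""
        V_V = 4.0 / 3.0 * math.pi * r**3
        V_m = 4.0 / 3.0 * math.pi * ((r + h) ** 3 - r**3)
        expected = 2.0 * (h / r) + (h / r) ** 2
        assert area_factor(V_m, V_V) == pytest.approx(expected, rel=1e-10)

    @given(st.floats(10.0, 500.0), st.floats(10.0, 500.0))
    @settings(derandomize=True, max_examples=100)
    def test_thickness_root_solves_cubic(self, V_m, V_V):
        """The closed-form h/r root substituted back reproduces V_m/V_V."""
        x = (V_m / V_V + 1.0) ** (1.0 / 3.0) - 1.0
        assert 3 * x + 3 * x**2 + x**3 == pytest.approx(V_m / V_V, rel=1e-10)


class TestActivation:
    def test_unity_at_peak(self):
        assert lv_activation(VENT.t_Vmax, VENT) == 1.0

    @pytest.mark.parametrize("delta", [0.05, 0.1, 0.2])
    def test_symmetric_about_peak(self, delta):
        assert lv_activation(VENT.t_Vmax - delta, VENT) == pytest.approx(
            lv_activation(VENT.t_Vmax + delta, VENT), rel=1e-12
        )

    def test_value_at_150_ms_offset(self):
        # direct evaluation of the double-exponential twitch
        expected = math.exp(
            -((5.68722 * 0.15) ** 2.0224) - (5.2270 * 0.15) ** 9.11538
        )
        assert lv_activation(VENT.t_Vmax + 0.15, VENT) == pytest.approx(expected)
        assert expected == pytest.approx(0.43, abs=0.01)

    def test_relaxed_within_cycle(self):
        """The twitch must die out within one 0.8333 s beat."""
        for delta in (0.36, 0.4, 0.45):
            assert lv_activation(VENT.t_Vmax + delta, VENT) < 0.01

    def test_atrial_twitch_peak_and_decay(self):
        assert atrial_activation(ATR.t_Amax, ATR) == 1.0
        assert atrial_activation(ATR.t_Amax + 0.1, ATR) < 1e-6


class TestEjectionDerating:
    def test_unity_at_end_diastolic_volume(self):
        assert ejection_derating(114.0, 114.0, VENT) == 1.0

    def test_clamped_during_filling(self):
        assert ejection_derating(120.0, 114.0, VENT) == 1.0

    def test_reference_value(self):
        expected = 1.0 - (1.0 / 1.355) * (-math.log(36.0 / 114.0)) ** 0.35
        assert ejection_derating(36.0, 114.0, VENT) == pytest.approx(expected)
        assert expected == pytest.approx(0.224, abs=0.001)

    def test_monotone_in_volume(self):
        assert ejection_derating(0.3 * 114, 114.0, VENT) < ejection_derating(
            0.6 * 114, 114.0, VENT
        )


class TestLVPressure:
    def test_diastole_reduces_to_passive(self):
        """Far from the activation peak the active term vanishes."""
        t = VENT.t_Vmax + 0.45
        assert lv_pressure(t, 90.0, 114.0, VENT) == pytest.approx(
            passive_lv_pressure(90.0, VENT), abs=1e-6
        )

    def test_full_activation_at_ed_volume_gives_isovolumic_maximum(self):
        p = lv_pressure(VENT.t_Vmax, 114.0, 114.0, VENT)
        assert p == pytest.approx(isovolumic_max_pressure(114.0, VENT), rel=1e-12)

    def test_affine_in_contractility(self):
        """K_Vc scales only the active term."""
        t, V, Ved = VENT.t_Vmax - 0.05, 100.0, 114.0
        vals = {}
        for k in (0.5, 0.982, 1.0):
            vals[k] = lv_pressure(t, V, Ved, VENT.model_copy(update={"K_Vc": k}))
        passive = passive_lv_pressure(V, VENT)
        slope1 = (vals[1.0] - passive) / 1.0
        assert vals[0.982] - passive == pytest.approx(0.982 * slope1, rel=1e-9)
        assert vals[0.5] - passive == pytest.approx(0.5 * slope1, rel=1e-9)

    @given(st.floats(0.0, 0.83), st.floats(40.0, 113.0))
    @settings(derandomize=True, max_examples=60)
    def test_bounded_by_curves_at_ed_volume(self, t, _v):
        """At V = V_Ved the pressure interpolates passive..isovolumic-max."""
        P = lv_pressure(t, 114.0, 114.0, VENT)
        lo = passive_lv_pressure(114.0, VENT)
        hi = isovolumic_max_pressure(114.0, VENT)
        assert lo - 1e-9 <= P <= hi + 1e-9

    def test_wall_stress_pressure_consistency(self):
        """P_V = sigma_V * A_V by definition."""
        t, V, Ved = 0.3, 80.0, 114.0
        sigma = lv_wall_stress(t, V, Ved, VENT)
        assert sigma * area_factor(VENT.V_m, V) == pytest.approx(
            lv_pressure(t, V, Ved, VENT), rel=1e-12
        )


class TestAtrialPressure:
    def test_passive_anchor(self):
        """At the anchor volume, with the twitch off, P_A = 30 mmHg."""
        t_off = ATR.t_Amax + 0.3
        assert la_pressure(t_off, 100.0, ATR) == pytest.approx(30.0, abs=1e-6)

    def test_active_peak_adds_7_5(self):
        assert la_pressure(ATR.t_Amax, 100.0, ATR) == pytest.approx(37.5)

    def test_zero_volume_passive(self):
        t_off = ATR.t_Amax + 0.3
        assert la_pressure(t_off, 0.0, ATR) == pytest.approx(0.0, abs=1e-6)


class TestParameterValidation:
    def test_derived_coefficients(self):
        assert VENT.a_V == pytest.approx(VENT.P_Ved_M / 200.0**3)
        assert VENT.b_V == pytest.approx(275.0 / 200.0**2)
        assert ATR.a_A == pytest.approx(30.0 / 100.0**5)

    def test_inverted_pressure_order_rejected(self):
        with pytest.raises(ValueError):
            VentricleParameters(P_Vivmax_M=30.0, P_Ved_M=40.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            VentricleParameters(k_V1=0.0)

    def test_unknown_field_rejected(self):
        with pytest.raises(Exception):
            VentricleParameters(k_V3=1.0)
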