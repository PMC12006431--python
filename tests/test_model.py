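"""Model-layer tests: gating, thermal scaling, inactivation, calibration."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from thermoclamp.model import (
    BoltzmannGating,
    ConditionPreset,
    InactivationParams,
    ThermalGatingProfile,
    available_presets,
    current_density_model,
    inactivation_time_course,
    load_preset,
    open_probability,
    preset_from_toml,
    preset_to_toml,
    thermal_conductance_scale,
)


class TestOpenProbability:
    def test_midpoint_symmetry(self):
        assert open_probability(0.0, BoltzmannGating(0.0, 25.0)) == pytest.approx(0.5)

    def test_saturation_limits(self):
        g = BoltzmannGating(-9.4, 42.6)
        assert open_probability(5000.0, g) == pytest.approx(1.0, abs=1e-12)
        assert open_probability(-5000.0, g) == pytest.approx(0.0, abs=1e-12)

    def test_against_high_precision_logistic(self):
        # independent arbitrary-precision evaluation of 1/(1+exp((V1/2-V)/k))
        z = (sympy.Rational(-94, 10) - sympy.Integer(-80)) / sympy.Rational(426, 10)
        expected = float((1 / (1 + sympy.exp(z))).evalf(30))
        got = open_probability(-80.0, BoltzmannGating(-9.4, 42.6))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.160, abs=5e-4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            open_probability(math.nan, BoltzmannGating(0.0, 25.0))
        with pytest.raises(ValueError):
            BoltzmannGating(0.0, -5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(vh=st.floats(-100, 100), k=st.floats(1.0, 60.0))
    def test_strictly_increasing_and_bounded(self, vh, k):
        g = BoltzmannGating(vh, k)
        v = np.linspace(-200, 200, 401)
        po = open_probability(v, g)
        assert np.all(po > 0) and np.all(po <= 1)
        assert np.all(np.diff(po) >= 0)
        # strict increase away from floating-point saturation
        interior = (po > 1e-12) & (po < 1 - 1e-12)
        if interior.sum() > 1:
            assert np.all(np.diff(po[interior]) > 0)

    def test_derivative_maximal_at_midpoint(self):
        g = BoltzmannGating(-20.0, 15.0)
        v = np.linspace(-120, 80, 2001)
        dpo = np.gradient(open_probability(v, g), v)
        assert abs(v[np.argmax(dpo)] - g.v_half_mv) < 0.2


class TestVHalfAtTemperature:
    def test_anchor_exact(self, ph74):
        g = ph74.gating
        assert g.v_half_at(22.0) == pytest.approx(-9.4, abs=1e-9)
        assert g.v_half_at(38.0) == pytest.approx(-85.5, abs=1e-9)

    def test_near_midpoint_at_transition_center(self, ph74):
        g = ph74.gating
        span = g.v_half_hot - g.v_half_cold
        frac = (g.v_half_at(g.transition_center) - g.v_half_cold) / span
        assert abs(frac - 0.5) < 0.06  # logistic centre, anchor-normalized

    def test_monotone_between_anchors(self, presets):
        for p in presets.values():
            t = np.linspace(22, 38, 200)
            vh = p.gating.v_half_at(t)
            d = np.diff(vh)
            # monotone toward the hot anchor (non-strict for flat profiles)
            span = p.gating.v_half_hot - p.gating.v_half_cold
            if span < 0:
                assert np.all(d <= 1e-12)
            elif span > 0:
                assert np.all(d >= -1e-12)


class TestThermalScale:
    def test_unity_at_reference(self, ba):
        assert thermal_conductance_scale(ba.gating.t_ref, ba.gating) == pytest.approx(1.0)

    def test_q10_definition_below_threshold(self):
        g = ThermalGatingProfile(0, 0, 25, 25, q10_slow=2.0, q10_steep=9.0,
                                 t_threshold=33.5, t_ref=22.0)
        assert thermal_conductance_scale(32.0, g) == pytest.approx(2.0, rel=1e-12)

    def test_piecewise_product_oracle(self, ph74):
        # independent high-precision evaluation of 2.7^1.15 * 5.01^0.45
        expected = float(
            (sympy.Rational(27, 10) ** sympy.Rational(115, 100)
             * sympy.Rational(501, 100) ** sympy.Rational(45, 100)).evalf(30)
        )
        got = thermal_conductance_scale(38.0, ph74.gating)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_threshold(self, ba):
        g = ba.gating
        eps = 1e-9
        lo = thermal_conductance_scale(g.t_threshold - eps, g)
        hi = thermal_conductance_scale(g.t_threshold + eps, g)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_two_point_formula_reconstructs_q10(self, ba):
        # below threshold, the two-point formula inverts the scale exactly
        g = ba.gating
        s1 = thermal_conductance_scale(24.0, g)
        s2 = thermal_conductance_scale(30.0, g)
        assert (s2 / s1) ** (10.0 / 6.0) == pytest.approx(g.q10_slow, rel=1e-12)

    def test_memoryless_reversibility(self, ba):
        # a heat-and-cool excursion leaves the scale unchanged
        g = ba.gating
        before = thermal_conductance_scale(26.0, g)
        for t in (30.0, 38.0, 41.0, 35.0, 26.0):
            thermal_conductance_scale(t, g)
        assert thermal_conductance_scale(26.0, g) == before


class TestInactivation:
    def test_initial_condition_and_none(self):
        p = InactivationParams(tau_ms=25.0, h_inf=0.35)
        assert inactivation_time_course(0.0, p) == 1.0
        none = InactivationParams(tau_ms=None)
        t = np.linspace(0, 500, 50)
        assert np.all(inactivation_time_course(t, none) == 1.0)

    def test_closed_form_at_tau(self):
        p = InactivationParams(tau_ms=30.0, h_inf=0.0)
        assert inactivation_time_course(30.0, p) == pytest.approx(math.exp(-1))

    def test_monotone_nonincreasing(self):
        p = InactivationParams(tau_ms=10.0, h_inf=0.2)
        h = inactivation_time_course(np.linspace(0, 200, 100), p)
        assert np.all(np.diff(h) <= 0)
        assert h[-1] == pytest.approx(0.2, abs=1e-6)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            InactivationParams(tau_ms=-1.0)
        with pytest.raises(ValueError):
            InactivationParams(tau_ms=10.0, h_inf=1.5)


class TestCurrentDensityModel:
    def test_zero_driving_at_reversal(self, presets):
        for p in presets.values():
            vr = p.permeation.v_rev_mv
            assert p.gated_density(vr, 30.0) == 0.0
            assert p.current_density(vr, 30.0) == pytest.approx(p.leak_density(vr))

    def test_all_anchors_reproduced(self, presets):
        # noise-free model hits every calibration anchor within 0.5%
        for p in presets.values():
            for a in p.permeation.anchors:
                pred = current_density_model(a.v_mv, a.temperature_c, 0.0, p,
                                             "peak", protocol=a.protocol)
                assert pred == pytest.approx(a.density_pa_pf, rel=5e-3), (
                    p.name, a)

    def test_null_preset_residual_leak(self, null):
        assert current_density_model(-80.0, 24.0, 0.0, null, "peak") == pytest.approx(-6.1)

    def test_ph74_hot_ramp_density(self, ph74):
        got = current_density_model(-80.0, 38.0, 0.0, ph74, "peak", protocol="ramp")
        assert got == pytest.approx(-271.81, rel=5e-3)

    def test_null_temperature_insensitive(self, null):
        v = np.linspace(-140, 80, 45)
        d = np.abs(null.current_density(v, 38.0) - null.current_density(v, 24.0))
        assert float(d.max()) <= 1.5

    def test_steady_phase_uses_h_inf(self, presets):
        p = presets["pH6.0"]
        peak = current_density_model(-80.0, 38.0, 0.0, p, "peak")
        steady = current_density_model(-80.0, 38.0, 0.0, p, "steady")
        gated_peak = peak - p.leak_density(-80.0)
        gated_steady = steady - p.leak_density(-80.0)
        assert gated_steady / gated_peak == pytest.approx(p.inactivation.h_inf)

    def test_sign_convention(self, ph74):
        assert current_density_model(-80.0, 24.0, 0.0, ph74, "peak") < 0
        assert current_density_model(+80.0, 24.0, 0.0, ph74, "peak") > 0


class TestPresets:
    def test_serialization_round_trip_exact(self, presets):
        for p in presets.values():
            assert preset_from_toml(preset_to_toml(p)) == p

    def test_all_seven_conditions_ship(self):
        assert len(available_presets()) == 7
        for name in available_presets():
            load_preset(name)

    def test_null_has_no_gated_conductance(self, null):
        assert null.permeation.anchors == ()
        v = np.linspace(-140, 80, 23)
        assert np.all(null.gated_density(v, 38.0) == 0.0)

    def test_cm_bounds_enforced(self, ph74):
        with pytest.raises(ValueError):
            ConditionPreset(
                name="bad", gating=ph74.gating, inactivation=ph74.inactivation,
                permeation=ph74.permeation, leak_density_pa_pf=-6.1,
                cm_mean_pf=5.0, cm_sd_pf=0.1, cell_scale_cv=0.2,
            )

    def test_anchor_sign_consistency_enforced(self, ph74):
        bad = preset_to_toml(ph74).replace("-143.54", "143.54")
        with pytest.raises(ValueError):
            preset_from_toml(bad)
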