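"""Johnson-Cook flow stress, damage, fitting and the tensile simulator."""

import math

import numpy as np
import pytest

import gelmech as g
from gelmech.johnson_cook import DamageState

from conftest import GEL_COLUMNS, make_material


class TestFlowStress:
    def test_at_reference_rate_and_zero_plastic_strain(self):
        mat = make_material("1:0")
        # both brackets collapse: sigma = A
        assert g.jc_stress(mat, 0.0, 1.0) == pytest.approx(2969e3)

    def test_hardening_term(self):
        mat = make_material("1:0")
        assert g.jc_stress(mat, 0.01, 1.0) == pytest.approx(5016.7e3, rel=1e-4)

    def test_rate_bracket(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=1e6, yield_strength=2969e3, rate_sensitivity=0.01
        )
        # ln(e) = 1 -> sigma = A * 1.01
        assert g.jc_stress(mat, 0.0, math.e) == pytest.approx(2998.69e3)

    def test_monotone_in_plastic_strain_and_rate(self):
        mat = make_material("0.5:0.5")
        eps = np.linspace(0, 0.2, 50)
        sig = g.jc_stress(mat, eps, 1.0)
        assert np.all(np.diff(sig) >= 0)
        rates = np.geomspace(1.0, 100.0, 20)
        sig_r = np.array([g.jc_stress(mat, 0.05, r) for r in rates])
        assert np.all(np.diff(sig_r) > 0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            g.jc_stress(make_material("1:0"), 0.0, 0.0)

    def test_sub_reference_rate_floored_with_warning(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=1e6, yield_strength=1e3, rate_sensitivity=0.5
        )
        with pytest.warns(RuntimeWarning, match="floored"):
            sig = g.jc_stress(mat, 0.0, 1e-5)
        assert sig > 0


class TestFractureStrain:
    def test_degenerate_constants_give_d1(self):
        mat = g.JohnsonCookMaterial(youngs_modulus=1e6, yield_strength=1e3, d1=0.07)
        for tri in (0.0, 1.0 / 3.0, 2.0):
            assert g.jc_fracture_strain(mat, tri, 5.0) == pytest.approx(0.07)

    def test_triaxiality_dependence(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=1e6, yield_strength=1e3, d1=0.05, d2=0.1, d3=1.0
        )
        assert g.jc_fracture_strain(mat, 0.0, 1.0) == pytest.approx(0.15)
        assert g.jc_fracture_strain(mat, 1.0 / 3.0, 1.0) == pytest.approx(
            0.12165, abs=1e-5
        )

    def test_nonpositive_fracture_strain_names_parameters(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=1e6, yield_strength=1e3, d1=-0.1
        )
        with pytest.raises(ValueError, match="d1=-0.1"):
            g.jc_fracture_strain(mat, 1.0 / 3.0, 1.0)


class TestDamageAccumulation:
    def test_constant_fracture_strain_integral(self):
        # monotonic flow to eps_p = eps_f in equal increments: D = 1 exactly
        # (increments chosen binary-exact so the float sum is exact too)
        state = DamageState()
        for _ in range(8):
            state = g.accumulate_damage(state, 0.04, 0.32)
        assert state.damage == 1.0
        assert state.failed

    def test_zero_increment_is_identity(self):
        state = DamageState(0.3)
        assert g.accumulate_damage(state, 0.0, 0.1).damage == 0.3

    def test_piecewise_fracture_strain(self):
        state = g.accumulate_damage(DamageState(), 0.05, 0.1)
        state = g.accumulate_damage(state, 0.05, 0.2)
        assert state.damage == pytest.approx(0.75)
        assert not state.failed

    def test_matches_brute_force_trapezoid_on_varying_path(self):
        eps_p = np.linspace(0, 0.08, 200)
        eps_f = 0.1 + 0.5 * eps_p  # fracture strain varying along the path
        expected = np.trapezoid(1.0 / eps_f, eps_p)
        assert g.damage_integral(eps_p, eps_f) == pytest.approx(
            expected, rel=1e-12
        )


class TestHardeningFit:
    @pytest.mark.parametrize("ratio", list(GEL_COLUMNS))
    def test_noiseless_recovery(self, ratio):
        col = GEL_COLUMNS[ratio]
        eps = np.linspace(1e-4, 0.1, 200)
        sig = col["A"] + col["B"] * eps ** col["n"]
        fit = g.fit_hardening(eps, sig)
        assert fit.yield_strength == pytest.approx(col["A"], rel=1e-2)
        assert fit.hardening_modulus == pytest.approx(col["B"], rel=1e-2)
        assert fit.hardening_exponent == pytest.approx(col["n"], rel=0.1)

    def test_constant_stress_has_vanishing_hardening(self):
        eps = np.linspace(1e-3, 0.1, 50)
        sig = np.full_like(eps, 683e3)
        fit = g.fit_hardening(eps, sig)
        hardening_span = fit.hardening_modulus * eps[-1] ** fit.hardening_exponent
        assert abs(hardening_span) < 1e-3 * 683e3

    def test_noisy_recovery_at_fixed_seed(self):
        col = GEL_COLUMNS["0.5:0.5"]
        rng = np.random.default_rng(42)
        eps = np.linspace(1e-3, 0.1, 200)
        sig = (col["A"] + col["B"] * eps ** col["n"]) * (
            1.0 + 0.01 * rng.standard_normal(eps.size)
        )
        fit = g.fit_hardening(eps, sig)
        assert fit.yield_strength == pytest.approx(col["A"], rel=0.05)

    def test_all_elastic_input_rejected(self):
        with pytest.raises(ValueError, match="post-yield"):
            g.fit_hardening(np.zeros(20), np.full(20, 1e3))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            g.fit_hardening(np.linspace(0.01, 0.1, 5), np.linspace(1, 2, 5))


class TestDamageFit:
    def test_noiseless_recovery_over_triaxialities(self):
        true = (0.05, 0.1, 1.0, 0.0)
        tris = [0.0, 1.0 / 3.0, 2.0 / 3.0]
        rates = [1.0, 10.0]
        obs = []
        for t in tris:
            for r in rates:
                f = (true[0] + true[1] * math.exp(-true[2] * t)) * (
                    1.0 + true[3] * math.log(r)
                )
                obs.append((f, t, r))
        d1, d2, d3, d4 = g.fit_damage(obs)
        assert d1 == pytest.approx(0.05, abs=1e-6)
        assert d2 == pytest.approx(0.1, abs=1e-6)
        assert d3 == pytest.approx(1.0, abs=1e-4)
        assert d4 == pytest.approx(0.0, abs=1e-6)

    def test_single_observation_with_only_d1_free(self):
        d1, d2, d3, d4 = g.fit_damage(
            [(0.08, 1.0 / 3.0, 1.0)], fixed={"d2": 0.0, "d3": 0.0, "d4": 0.0}
        )
        assert d1 == pytest.approx(0.08)

    def test_unidentifiable_design_raises(self):
        obs = [(0.05, 1.0 / 3.0, 1.0), (0.06, 1.0 / 3.0, 2.0)]
        with pytest.raises(ValueError, match="d3"):
            g.fit_damage(obs)


class TestTensileSimulator:
    def test_elastic_limit_is_censored_line(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=1e6, yield_strength=1e12, d1=0.05
        )
        prog = g.LoadingProgram(strain_rate=0.033, duration=3.0, step=0.03)
        curve, state = g.simulate_tensile(mat, prog)
        assert not state.failed
        assert curve.failure_index is None
        slope = np.polyfit(curve.strain, curve.stress, 1)[0]
        assert slope == pytest.approx(1e6, rel=1e-3)

    def test_constant_fracture_strain_fails_within_one_step(self):
        mat = g.JohnsonCookMaterial(
            youngs_modulus=10e6,
            yield_strength=500e3,
            hardening_modulus=1e6,
            hardening_exponent=0.5,
            d1=0.05,
        )
        rate = 0.033
        step_strain = 1e-3
        prog = g.LoadingProgram(
            strain_rate=rate, duration=10.0, step=step_strain / rate
        )
        curve, state = g.simulate_tensile(mat, prog)
        assert state.failed
        eps_p_final = curve.strain[-1] - curve.stress[-1] / mat.youngs_modulus
        assert eps_p_final == pytest.approx(0.05, abs=step_strain)

    def test_failure_stress_consistent_with_flow_stress(self):
        mat = make_material("1:0", d1=0.03)
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=30.0, step=5e-4 / rate)
        curve, state = g.simulate_tensile(mat, prog)
        assert state.failed
        expected = g.jc_stress(mat, 0.03, rate)
        assert curve.stress[-1] == pytest.approx(expected, rel=0.02)

    def test_pre_yield_slope_equals_modulus(self):
        mat = make_material("0.5:0.5", d1=0.1)
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=30.0, step=1e-3 / rate)
        curve, _ = g.simulate_tensile(mat, prog)
        yield_strain = mat.yield_strength / mat.youngs_modulus
        mask = (curve.strain > 0) & (curve.strain < 0.5 * yield_strain)
        slopes = curve.stress[mask] / curve.strain[mask]
        np.testing.assert_allclose(slopes, mat.youngs_modulus, rtol=1e-3)

    def test_post_yield_stress_on_hardening_curve(self):
        mat = make_material("0.75:0.25", d1=0.2)
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=30.0, step=1e-3 / rate)
        curve, _ = g.simulate_tensile(mat, prog)
        eps_p = curve.strain - curve.stress / mat.youngs_modulus
        mask = eps_p > 1e-6
        expected = g.jc_stress(mat, eps_p[mask], rate)
        np.testing.assert_allclose(curve.stress[mask], expected, rtol=1e-8)

    def test_damage_matches_brute_force_quadrature(self):
        mat = make_material("0.5:0.5", d1=0.04)
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=30.0, step=1e-3 / rate)
        curve, state = g.simulate_tensile(mat, prog)
        eps_p = np.maximum(curve.strain - curve.stress / mat.youngs_modulus, 0.0)
        eps_f = np.array(
            [
                g.jc_fracture_strain(mat, g.UNIAXIAL_TRIAXIALITY, rate)
                for _ in eps_p
            ]
        )
        brute = np.trapezoid(1.0 / eps_f, eps_p)
        assert state.damage == pytest.approx(brute, rel=1e-6)

    def test_area_under_curve_increases_with_fracture_strain(self):
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=60.0, step=1e-3 / rate)
        areas = []
        for d1 in (0.02, 0.05, 0.1):
            mat = make_material("0.5:0.5", d1=d1)
            curve, state = g.simulate_tensile(mat, prog)
            assert state.failed
            areas.append(np.trapezoid(curve.stress, curve.strain))
        assert areas[0] > 0
        assert areas[0] < areas[1] < areas[2]

    def test_round_trip_parameter_recovery(self):
        """simulate (no damage) -> decompose -> fit recovers (A, B, n)."""
        mat = make_material("0.5:0.5")
        rate = 0.033
        prog = g.LoadingProgram(strain_rate=rate, duration=10.0, step=1e-4 / rate)
        curve, _ = g.simulate_tensile(mat, prog, with_damage=False)
        eps_p = curve.strain - curve.stress / mat.youngs_modulus
        mask = eps_p > 1e-8
        # stress at reference rate: undo the rate bracket
        bracket = 1.0 + mat.rate_sensitivity * math.log(rate / mat.ref_rate)
        fit = g.fit_hardening(eps_p[mask], curve.stress[mask] / bracket)
        assert fit.yield_strength == pytest.approx(mat.yield_strength, rel=0.01)
        assert fit.hardening_modulus == pytest.approx(
            mat.hardening_modulus, rel=0.01
        )
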