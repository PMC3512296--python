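"""Linearized step response, quadrature oracle, and scaling laws."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import hillchain as hc
from hillchain import SMALL, BIG

P1 = SMALL.ce_parameters(1)
PB = BIG.ce_parameters(1)


class TestTau:
    def test_printed_time_constants(self):
        # whole muscle mass accelerated by one CE
        assert hc.tau_linearized(SMALL.mass, P1, 0.0) == pytest.approx(3.0e-6, rel=0.02)
        assert hc.tau_linearized(SMALL.mass, P1, 10.0) == pytest.approx(3.6e-4, rel=0.01)
        assert hc.tau_linearized(BIG.mass, PB, 10.0) == pytest.approx(3.6e-2, rel=0.01)

    def test_isometric_to_unloaded_ratio_exact(self):
        # (1 + 1/A_rel)^2 = 121: the inertial response spans two orders of
        # magnitude across the concentric branch
        ratio = hc.tau_linearized(1.0, P1, 10.0) / hc.tau_linearized(1.0, P1, 0.0)
        assert ratio == pytest.approx(121.0, rel=1e-12)

    def test_equals_mass_over_finite_difference_slope(self):
        for u0 in (0.0, 2.5, 10.0, 30.0):
            h = 1e-7 * P1.vmax_opt
            v = -u0 * P1.l_opt
            fd = (hc.ce_force(P1.l_opt, v + h, P1) - hc.ce_force(P1.l_opt, v - h, P1)) / (
                2 * h
            )
            assert hc.tau_linearized(0.01, P1, u0) == pytest.approx(0.01 / fd, rel=1e-6)

    def test_strictly_increasing_along_concentric_branch(self):
        u = np.linspace(0, 20, 50)
        tau = np.array([hc.tau_linearized(1.0, P1, ui) for ui in u])
        assert np.all(np.diff(tau) > 0)

    def test_rejects_non_positive_mass(self):
        with pytest.raises(ValueError):
            hc.tau_linearized(0.0, P1, 1.0)


class TestStepResponse:
    def test_exponential_decay_structure(self):
        resp = hc.step_response_linearized(SMALL.mass, P1, u0=0.0, f_external=0.0)
        assert resp.velocity(0.0) == pytest.approx(0.0)
        v_inf = resp.velocity(50 * resp.tau)
        assert v_inf == pytest.approx(resp.v_limit, rel=1e-12)
        # residual falls to 1/e at t = tau
        r0 = resp.v_limit - resp.velocity(0.0)
        r1 = resp.v_limit - resp.velocity(resp.tau)
        assert r1 / r0 == pytest.approx(np.exp(-1), rel=1e-12)
        # monotone, no overshoot
        v = resp.velocity(np.linspace(0, 10 * resp.tau, 200))
        assert np.all(np.diff(v) > 0)
        assert np.all(v <= resp.v_limit + 1e-15)

    def test_equilibrium_is_fixed_point(self):
        # external force equal to the operating-point force: no motion of
        # the linearized state
        u0 = 4.0
        f0 = hc.ce_force(P1.l_opt, -u0 * P1.l_opt, P1)
        resp = hc.step_response_linearized(SMALL.mass, P1, u0=u0, f_external=f0)
        assert resp.v_limit == pytest.approx(u0 * P1.l_opt, rel=1e-12)

    @pytest.mark.parametrize("u0", [0.0, 3.0, 8.0])
    def test_matches_nonlinear_relaxation_rate(self, u0):
        # a 1% velocity perturbation around an equilibrium held by a
        # matching external force relaxes at 1/tau to within 2%
        m = SMALL.mass
        f_ext = hc.ce_force(P1.l_opt, -u0 * P1.l_opt, P1)
        tau = hc.tau_linearized(m, P1, u0)
        delta0 = 0.01 * (u0 + 1.0)

        def rhs(t, y):
            return [(hc.ce_force(P1.l_opt, -y[0] * P1.l_opt, P1) - f_ext) / (m * P1.l_opt)]

        sol = solve_ivp(
            rhs, (0, tau), [u0 + delta0], rtol=1e-12, atol=1e-14, dense_output=True
        )
        d1 = sol.sol(0.25 * tau)[0] - u0
        d2 = sol.sol(0.75 * tau)[0] - u0
        rate = np.log(d1 / d2) / (0.5 * tau)
        assert rate == pytest.approx(1.0 / tau, rel=0.02)


class TestQuadratureOracle:
    def test_zero_target_zero_time(self):
        assert hc.single_mass_quadrature(SMALL.mass, P1, 0.0) == 0.0

    def test_closed_form_cross_check(self):
        # for A_rel = 0.1, B_rel = 1: t(u) = (M l/F) * 10*(11*ln w - 10*w)
        # evaluated between w = 1 - u/10 and w = 1
        u = 9.9
        w = 1.0 - u / 10.0
        closed = 10.0 * ((11 * np.log(1.0) - 10.0) - (11 * np.log(w) - 10.0 * w))
        expect = SMALL.mass * P1.l_opt / SMALL.f_max * closed  # 1.3246e-3 s
        got = hc.single_mass_quadrature(SMALL.mass, P1, u)
        assert got == pytest.approx(expect, rel=1e-9)
        assert got == pytest.approx(1.32e-3, rel=5e-3)

    def test_linear_in_mass(self):
        t_full = hc.single_mass_quadrature(SMALL.mass, P1, 7.0)
        t_half = hc.single_mass_quadrature(SMALL.mass / 2, P1, 7.0)
        assert t_half == pytest.approx(t_full / 2, rel=1e-12)

    def test_domain_error_at_zero_force_rate(self):
        with pytest.raises(ValueError):
            hc.single_mass_quadrature(SMALL.mass, P1, 10.0)

    def test_rate_at_time_inverts_quadrature(self):
        from scipy.optimize import brentq

        m = SMALL.mass / 2
        times = np.array([1e-5, 1e-4, 5e-4, 1.5e-3])
        u = hc.single_mass_rate_at_time(m, P1, times)
        direct = np.array(
            [
                # bracket top reaches ~2.7 ms, beyond every queried time
                brentq(
                    lambda x: hc.single_mass_quadrature(m, P1, x) - t,
                    0.0,
                    10.0 * (1 - 1e-7),
                    xtol=1e-15,
                    rtol=8.9e-16,
                )
                for t in times
            ]
        )
        np.testing.assert_allclose(u, direct, rtol=1e-7)


class TestGeometricScaling:
    def test_small_times_ten_ten_is_big(self):
        scaled = hc.geometric_scale(SMALL, 10.0, 10.0)
        assert scaled.mass == pytest.approx(BIG.mass, rel=1e-15)
        assert scaled.f_max == pytest.approx(BIG.f_max, rel=1e-15)
        assert scaled.l_m_opt == pytest.approx(BIG.l_m_opt, rel=1e-15)
        assert scaled.v_m_max0 == pytest.approx(BIG.v_m_max0, rel=1e-15)
        assert (scaled.a_rel, scaled.b_rel) == (BIG.a_rel, BIG.b_rel)

    def test_identity_scaling(self):
        assert hc.geometric_scale(SMALL, 1.0, 1.0) == SMALL

    def test_time_scale_factor_hundredfold(self):
        scaled = hc.geometric_scale(SMALL, 10.0, 10.0)
        t_small = SMALL.mass * SMALL.l_m_opt / SMALL.f_max
        t_big = scaled.mass * scaled.l_m_opt / scaled.f_max
        assert t_big / t_small == pytest.approx(100.0, rel=1e-12)

    def test_tau_fiber_length_consistency(self):
        ctx = hc.ScalingContext.from_preset(SMALL)
        # reproduces the mass-based time constant when the substitution is
        # exact (piglet-derived rho/sigma with the big fibre length)
        tau = hc.tau_fiber_length(0.15, ctx, P1, 10.0)
        assert tau == pytest.approx(3.6e-2, rel=0.01)
        assert tau == pytest.approx(hc.tau_linearized(BIG.mass, PB, 10.0), rel=1e-12)

    def test_tau_quadratic_in_fibre_length(self):
        ctx = hc.ScalingContext.from_preset(SMALL)
        t1 = hc.tau_fiber_length(0.02, ctx, P1, 5.0)
        t2 = hc.tau_fiber_length(0.04, ctx, P1, 5.0)
        assert t2 / t1 == pytest.approx(4.0, rel=1e-12)


class TestPropagationTime:
    def test_printed_values(self):
        assert hc.propagation_time(0.015) == pytest.approx(3.8e-3, rel=0.02)
        assert hc.propagation_time(0.15) == pytest.approx(3.8e-2, rel=0.02)
        assert hc.propagation_time(0.0) == 0.0

    def test_excitation_vs_inertia_crossover(self):
        # short fibres: excitation propagation is the slower process;
        # at 15 cm the inertial time constant catches up with it
        tau_small = hc.tau_linearized(SMALL.mass, P1, 10.0)
        assert hc.propagation_time(0.015) / tau_small > 5
        tau_big = hc.tau_linearized(BIG.mass, PB, 10.0)
        assert hc.propagation_time(0.15) == pytest.approx(tau_big, rel=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hc.propagation_time(-1.0)
        with pytest.raises(ValueError):
            hc.propagation_time(0.015, c=0.0)
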