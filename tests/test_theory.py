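"""Reduced-model theory: knees, averages, dead-time rate approximation."""

import numpy as np
import pytest

from gainswitch.params import reduced_params
from gainswitch.inputs import generate_periodic_train
from gainswitch import theory
from gainswitch.theory import (KneeNotFoundError, N_lk, b_average, b_star_E,
                               b_star_I, build_context, deadtime_rate,
                               find_knee, firing_threshold, fit_refractory_R,
                               gamma_curve, n_map, nullcline_branch,
                               nullcline_n, onset_slope, quasi_steady_V,
                               rho_fraction, sigma_star, theory_rate_curve,
                               theta_map)

RP = reduced_params()


class TestSigmaStar:
    def test_closed_form_values(self):
        assert sigma_star(0.18, 50.0) == pytest.approx(np.exp(-3.6))
        assert sigma_star(0.18, 70.0) == pytest.approx(np.exp(-0.18 * 1000 / 70))

    def test_no_decay_limit(self):
        assert sigma_star(1e-9, 50.0) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_rate_raises(self):
        from gainswitch.params import InvalidParameterError
        with pytest.raises(InvalidParameterError):
            sigma_star(0.18, 0.0)


class TestQuasiSteadyVoltage:
    def test_leak_only(self):
        assert quasi_steady_V(0.0, 0.0, RP) == pytest.approx(-70.0)

    def test_full_excitation(self):
        # g_L = 1, g_synE = 3: (-70 + 0) / 4
        assert quasi_steady_V(1.0, 0.0, RP) == pytest.approx(-17.5)

    def test_full_inhibition(self):
        # g_L = 1, g_synI = 5: (-70 + 5 * (-85)) / 6
        assert quasi_steady_V(0.0, 1.0, RP) == pytest.approx(-82.5)


class TestRhoAndDeadtime:
    def test_rho_endpoints_exact(self):
        P_I, beta_I = 20.0, 0.18
        assert rho_fraction(1.0, P_I, beta_I) == 1.0
        assert rho_fraction(sigma_star(beta_I, 50.0), P_I, beta_I) == 0.0

    def test_rho_half_period(self):
        P_I, beta_I = 20.0, 0.18
        assert rho_fraction(np.exp(-P_I * beta_I / 2), P_I, beta_I) \
            == pytest.approx(0.5)

    def test_deadtime_rate_values(self):
        assert deadtime_rate(0.0, 10.0) == 0.0
        assert deadtime_rate(42.0, 0.0) == pytest.approx(42.0)
        assert deadtime_rate(100.0, 10.0) == pytest.approx(50.0)

    def test_refractory_fit_recovers_exact_data(self):
        r_E = np.arange(10.0, 151.0, 10.0)
        assert fit_refractory_R(r_E, deadtime_rate(r_E, 8.0)) \
            == pytest.approx(8.0, abs=0.01)
        assert fit_refractory_R(r_E, r_E) == pytest.approx(0.0, abs=0.01)


class TestBAverages:
    def test_b_at_rest_is_one_half(self):
        # theta_b equals the leak reversal, so b relaxes to exactly 1/2
        assert b_star_E(0.0, RP) == pytest.approx(0.5)

    def test_b_av_at_zero_rate_equals_inhibitory_component(self):
        bI = b_star_I(RP, r_I=50.0)
        assert b_average(0.0, "reduced", RP) == pytest.approx(bI, abs=1e-9)

    def test_inhibition_primes_b_above_resting_level(self):
        assert b_star_I(RP, r_I=50.0) > 0.5

    def test_reduced_average_decreases_with_excitation_rate(self):
        vals = [b_average(r, "reduced", RP, duration=40_000.0, seed=6)
                for r in (0.0, 30.0, 60.0, 100.0)]
        assert np.all(np.diff(vals) < 0)

    def test_time_average_matches_renewal_expectation(self):
        # for Poisson drive, time since the last event is Exp(r_E), giving a
        # closed-form stationary average of b_inf(V_E(s_E)) that the long
        # scalar simulation must reproduce (the b ODE is linear with a
        # constant time constant, so <b> -> <b_inf> over long windows)
        from scipy.integrate import quad
        from gainswitch.model import gate_steady_state
        r_E = 40.0
        rate_ms = r_E / 1000.0

        def b_inf_of_age(age):
            V = quasi_steady_V(np.exp(-RP.beta_E * age), 0.0, RP)
            return gate_steady_state("b", V, RP)

        expected, _ = quad(lambda u: rate_ms * np.exp(-rate_ms * u)
                           * b_inf_of_age(u), 0.0, 2000.0, limit=200)
        simulated = b_star_E(r_E, RP, duration=150_000.0, seed=8)
        assert simulated == pytest.approx(expected, abs=0.01)


class TestNullclineAndKnees:
    def test_roots_satisfy_the_nullcline_equation(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            V = rng.uniform(-78.0, 0.0)
            b = rng.uniform(0.2, 0.9)
            sI = rng.uniform(0.0, 1.0)
            gA = rng.uniform(0.0, 45.0)
            roots = nullcline_n(V, b, 1.0, sI, gA, RP)
            A, B, C = theory._quartic_coeffs(V, b, 1.0, sI, gA, RP)
            for n in roots:
                assert abs(A * n ** 4 + B * n + C) < 1e-8 * (abs(A) + abs(B) + abs(C))

    def test_branch_equals_largest_real_root(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            V = rng.uniform(-78.0, -25.0)
            b = rng.uniform(0.3, 0.9)
            sI = rng.uniform(0.0, 0.5)
            gA = rng.uniform(0.0, 35.0)
            roots = nullcline_n(V, b, 1.0, sI, gA, RP)
            branch = nullcline_branch(V, b, 1.0, sI, gA, RP)[0]
            if roots.size:
                assert branch == pytest.approx(roots.max(), abs=1e-8)
            else:
                assert np.isnan(branch)

    def test_left_knee_monotonicities(self, reduced_ctx):
        ss = reduced_ctx.sigma_star
        # decreasing in g_A
        knees_gA = [N_lk(ss, 0.0, g, reduced_ctx) for g in (10, 20, 25, 30)]
        assert np.all(np.diff(knees_gA) < 0)
        # increasing in r_E (through the falling b average)
        knees_rE = [N_lk(ss, r, 32.0, reduced_ctx) for r in (0, 30, 60, 100)]
        assert np.all(np.diff(knees_rE) > 0)
        # decreasing in s_I
        knees_sI = [N_lk(s, 0.0, 20.0, reduced_ctx)
                    for s in (ss, 0.1, 0.3, 0.6)]
        assert np.all(np.diff(knees_sI) < 0)
        # decreasing in b, increasing in s_E (directly on the knee finder)
        kb = [find_knee(b, 1.0, 0.2, 20.0, RP).n for b in (0.4, 0.6, 0.8)]
        assert np.all(np.diff(kb) < 0)
        ke = [find_knee(0.6, sE, 0.2, 20.0, RP).n for sE in (0.6, 0.8, 1.0)]
        assert np.all(np.diff(ke) > 0)

    def test_no_knee_error_when_branch_is_monotone(self):
        # without the sodium and A currents the driven nullcline branch is
        # strictly decreasing across the window: no fold to find
        p = RP.replace(g_Na=0.0, g_A=0.0)
        with pytest.raises(KneeNotFoundError):
            find_knee(0.5, 1.0, 0.0, 0.0, p, side="left")


class TestCriticalConductanceAndGamma:
    def test_knee_vanishes_at_critical_conductance(self, reduced_ctx):
        gA0 = theory.critical_gA(reduced_ctx)
        assert abs(N_lk(reduced_ctx.sigma_star, 0.0, gA0, reduced_ctx)) < 5e-3

    def test_stronger_inhibition_lowers_the_critical_conductance(self, reduced_ctx):
        stronger = build_context(RP.replace(g_syn_I=6.0), r_I=50.0,
                                 r_E_grid=[0.0, 50.0], R=10.0,
                                 b_duration=20_000.0)
        assert theory.critical_gA(stronger) < theory.critical_gA(reduced_ctx)

    def test_gamma_continuous_at_transition_and_increasing(self, reduced_ctx):
        gA0 = theory.critical_gA(reduced_ctx)
        assert gamma_curve(gA0 - 1.0, reduced_ctx) == 0.0
        g_small = gamma_curve(gA0 + 0.2, reduced_ctx)
        assert 0.0 < g_small < 15.0
        gammas = [gamma_curve(g, reduced_ctx) for g in (31.0, 34.0, 38.0)]
        assert np.all(np.diff(gammas) > 0)


class TestFiringThreshold:
    def test_fixed_point_residual_is_small(self, reduced_ctx):
        for g_A, r_E in ((15.0, 20.0), (25.0, 60.0), (35.0, 100.0)):
            theta, n_star = firing_threshold(r_E, g_A, reduced_ctx)
            composed = n_map(theta, r_E, g_A, reduced_ctx)
            assert abs(n_star - composed) < 1e-6

    def test_fixed_point_exists_across_the_parameter_plane(self, reduced_ctx):
        for g_A in (5.0, 15.0, 25.0, 35.0):
            for r_E in (5.0, 40.0, 120.0):
                theta, n_star = firing_threshold(r_E, g_A, reduced_ctx)
                assert 0.0 < theta <= 1.0
                assert 0.0 <= n_star <= 1.0

    def test_weak_A_current_gives_nearly_constant_threshold(self, reduced_ctx):
        grid = np.arange(10.0, 151.0, 20.0)
        th15 = np.array([firing_threshold(r, 15.0, reduced_ctx)[0]
                         for r in grid])
        th35 = np.array([firing_threshold(r, 35.0, reduced_ctx)[0]
                         for r in grid])
        assert th15.max() - th15.min() < 0.2      # nearly constant
        assert th35.max() - th35.min() > th15.max() - th15.min()
        assert th35[-1] > th35[0]                 # rises with input rate

    def test_no_inhibition_limit_reproduces_pure_deadtime_rate(self, reduced_ctx):
        grid = np.array([20.0, 60.0, 120.0])
        # with theta = 1 the thinning factor is 1 and the rate is Eq-12-like
        expected = deadtime_rate(grid, reduced_ctx.R)
        rho1 = np.array([rho_fraction(1.0, reduced_ctx.P_I, RP.beta_I)])
        assert rho1[0] == 1.0
        curve = np.array([deadtime_rate(r, reduced_ctx.R, 1.0) for r in grid])
        np.testing.assert_allclose(curve, expected)

    def test_theory_curves_show_divisive_to_subtractive_transition(self, reduced_ctx):
        grid = np.arange(5.0, 121.0, 5.0)
        c15 = theory_rate_curve(grid, 15.0, reduced_ctx)
        c35 = theory_rate_curve(grid, 35.0, reduced_ctx)
        # divisive: responsive at the lowest rates
        assert c15[0] > 0.0
        # subtractive: a dead zone followed by recovery
        assert c35[0] == 0.0
        assert c35[-1] > 0.0
        dead_edge = grid[np.argmax(c35 > 0.0)]
        assert dead_edge > 10.0


class TestOnsetSlope:
    def test_near_unit_slope_without_A_current(self, reduced_ctx):
        # without I_A only the strongest shunting phase of each inhibitory
        # cycle can block spiking, so the onset slope sits just below 1
        s = onset_slope(0.0, reduced_ctx)
        assert 0.9 < s <= 1.0

    def test_slope_decreases_with_A_conductance(self, reduced_ctx):
        slopes = [onset_slope(g, reduced_ctx) for g in (0.0, 10.0, 20.0, 27.0)]
        assert np.all(np.diff(slopes) <= 1e-12)
        assert slopes[-1] < slopes[0]
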