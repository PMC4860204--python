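"""Tests for the analytic periodic solution, f-I curve, and noise sensitivity."""

import numpy as np
import pytest

from matreduce.analytics import (
    current_for_rate,
    eta_T_inf,
    eta_T_inf_slope,
    fi_adaptive,
    fi_closed_form,
    noise_sensitivity,
)
from matreduce.exceptions import BracketError
from matreduce.mat_model import MATParams, ThresholdKernel, threshold_kernel_eval


M_KERNEL = ThresholdKernel(alpha_0=36.0, tau_fast=10.0, alpha_m=1.6, tau_p=150.0)
M_MAT = MATParams(theta_inf=31.0, kernel=M_KERNEL)


class TestEtaTInf:
    def test_hand_evaluated_value(self):
        # alpha_0=35, tau_m=10, T=t=100: 35 e^{-10}/(1-e^{-10})
        k = ThresholdKernel(alpha_0=35.0, tau_fast=10.0)
        expected = 35.0 * np.exp(-10.0) / (1.0 - np.exp(-10.0))
        assert eta_T_inf(k, 100.0, 100.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.589e-3, rel=1e-3)

    def test_infinite_period_limit_is_kernel(self):
        k = ThresholdKernel(alpha_0=30.0, alpha_m=3.0, alpha_ahp=1.5,
                            tau_ca=200.0, tau_s=50.0)
        for t in (5.0, 50.0, 300.0):
            assert eta_T_inf(k, 1e9, t) == pytest.approx(
                threshold_kernel_eval(k, t), rel=1e-12
            )

    def test_matches_brute_force_periodic_sum(self):
        k = ThresholdKernel(alpha_0=35.0, alpha_m=4.0, tau_p=150.0,
                            alpha_ahp=2.0, tau_ca=200.0, tau_s=50.0)
        T = 73.0
        ks = np.arange(10001)
        for t in (1.0, 20.0, T):
            brute = threshold_kernel_eval(k, t + ks * T).sum()
            assert abs(eta_T_inf(k, T, t) - brute) < 1e-8

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            eta_T_inf(M_KERNEL, 0.0, 1.0)


class TestFICurve:
    def test_closed_form_hand_value(self):
        # theta=29, alpha_0=35, tau_m=10, I_0 tau_m = 64 -> f = 100/ln 2
        f = fi_closed_form(29.0, 35.0, 10.0, 6.4)
        assert f == pytest.approx(100.0 / np.log(2.0), rel=1e-12)
        assert f == pytest.approx(144.3, abs=0.1)

    def test_subthreshold_gives_zero(self):
        assert fi_closed_form(29.0, 35.0, 10.0, 2.8) == 0.0
        sol = fi_adaptive(M_MAT, 2.0)
        assert sol.f_hz == 0.0 and not np.isfinite(sol.period)

    def test_rate_vanishes_logarithmically_at_rheobase(self):
        # f -> 0 as I_0 tau_m -> theta_inf+, but only like 1/log(1/eps)
        for eps in (1e-3, 1e-6, 1e-9):
            f = fi_closed_form(29.0, 35.0, 10.0, 2.9 + eps)
            asymptote = 1000.0 / (10.0 * np.log(35.0 / (10.0 * eps)))
            assert f == pytest.approx(asymptote, rel=0.01)
        assert fi_closed_form(29.0, 35.0, 10.0, 2.9 + 1e-9) < fi_closed_form(
            29.0, 35.0, 10.0, 2.9 + 1e-3
        )

    def test_root_solution_equals_closed_form_without_slow_terms(self):
        mat = MATParams(theta_inf=29.0, kernel=ThresholdKernel(alpha_0=35.0))
        for i_0 in (3.2, 4.0, 6.4, 20.0):
            f_root = fi_adaptive(mat, i_0).f_hz
            f_cf = fi_closed_form(29.0, 35.0, 10.0, i_0)
            assert f_root == pytest.approx(f_cf, rel=1e-6)

    def test_periodic_residual_satisfied(self):
        sol = fi_adaptive(M_MAT, 5.0)
        assert sol.residual < 1e-6

    def test_rate_monotone_in_current(self):
        i0s = np.linspace(3.2, 12.0, 15)
        fs = [fi_adaptive(M_MAT, i).f_hz for i in i0s]
        assert np.all(np.diff(fs) > 0)

    def test_analytic_rate_matches_simulation(self, rng):
        # random kernels x currents: asymptotic simulated ISI vs analytic T
        from matreduce.mat_model import simulate_mat

        for _ in range(6):
            k = ThresholdKernel(
                alpha_0=rng.uniform(20, 40),
                alpha_m=rng.uniform(0, 5),
                tau_p=rng.uniform(100, 300),
                alpha_ahp=rng.uniform(0, 3),
                tau_ca=200.0,
                tau_s=rng.uniform(30, 120),
            )
            mat = MATParams(theta_inf=rng.uniform(20, 35), kernel=k)
            for f_target in (5.0, 20.0, 50.0):
                i_0 = current_for_rate(mat, f_target)
                sol = fi_adaptive(mat, i_0)
                sp, _, _ = simulate_mat(mat, np.full(int(30000 / 0.025), i_0), 0.025)
                f_sim = 1000.0 / sp.isis[-20:].mean()
                assert f_sim == pytest.approx(sol.f_hz, rel=0.02)


class TestNoiseSensitivity:
    def test_slope_negative_on_stable_orbit(self):
        ns = noise_sensitivity(M_MAT, 5.0)
        assert ns.slope < 0
        assert ns.delta_t < 0  # upward u-perturbation advances the next spike

    def test_matches_finite_difference_of_fi_curve(self):
        # Lowering theta_inf by delta_u is the same perturbation as raising
        # u.  The single-interval sensitivity equals the full periodic
        # finite difference up to a factor (1 - e^{-T/tau_m}) (the
        # perturbed history feeds back into the threshold), so the two
        # agree in the T >> tau_m regime.
        mat = MATParams(theta_inf=29.0, kernel=ThresholdKernel(alpha_0=35.0))
        i_0 = 3.0  # T = 10 ln(36) ~ 36 ms >> tau_m
        du = 0.01
        T0 = fi_adaptive(mat, i_0).period
        T1 = fi_adaptive(mat.replace(theta_inf=29.0 - du), i_0).period
        ns = noise_sensitivity(mat, i_0, delta_u=du)
        assert ns.delta_t == pytest.approx(T1 - T0, rel=0.05)

    def test_matches_single_bump_simulation(self):
        # A potential bump decays with tau_m, so it must be injected close
        # to the upcoming spike; the decay to the unperturbed spike time is
        # compensated analytically before comparing with the predicted delta_T.
        from matreduce.mat_model import simulate_mat

        mat = M_MAT
        i_0 = current_for_rate(mat, 20.0)
        sol = fi_adaptive(mat, i_0)
        dt = 0.025
        cur = np.full(int(20000 / dt), i_0)
        sp0, _, _ = simulate_mat(mat, cur, dt)
        du = 0.05  # mV, one-sample charge du * C_m / dt
        lead = 2.0  # ms before the expected next spike
        t_bump = sp0.times[-10] + sol.period - lead
        cur_b = cur.copy()
        cur_b[int(round(t_bump / dt))] += du * mat.c_m / dt
        sp1, _, _ = simulate_mat(mat, cur_b, dt)
        k = np.searchsorted(sp0.times, t_bump)
        shift = sp1.times[k] - sp0.times[k]
        du_eff = du * np.exp(-lead / mat.tau_m)
        ns = noise_sensitivity(mat, i_0, delta_u=du_eff)
        assert shift == pytest.approx(ns.delta_t, abs=max(0.15 * abs(ns.delta_t), 2 * dt))

    def test_subthreshold_current_rejected(self):
        with pytest.raises(BracketError):
            noise_sensitivity(M_MAT, 1.0)
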