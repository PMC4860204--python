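"""Tests for threshold probing and spike-triggered kernel extraction."""

import numpy as np
import pytest

from matreduce.exceptions import BracketError
from matreduce.fixtures import ahp_neuron, m_neuron, no_adaptation_neuron
from matreduce.hh_core import ConductanceParams, steady_state
from matreduce.threshold_probe import (
    HoldingProtocol,
    SpikeTriggeredResult,
    _spikes_from_shift,
    alpha_scaling_predictor,
    fit_eta,
    fit_h,
    instantaneous_threshold_from_state,
    postspike_threshold_curve,
    spike_triggered_current,
    threshold_variation_h,
)


@pytest.fixture(scope="module")
def m_protocol():
    return HoldingProtocol(m_neuron(g_m=0.1), v_c=-70.0, duration=600.0)


class TestBisectionProbe:
    def test_unexcitable_membrane_raises_bracket_error(self):
        p = ConductanceParams(g_na=0, g_kd=0, g_m=0, g_ca=0, g_ahp=0)
        state = steady_state(p, 0.0)
        background = np.zeros(2001)
        with pytest.raises(BracketError):
            instantaneous_threshold_from_state(p, state, background)

    def test_probe_is_deterministic(self, m_protocol):
        t0 = m_protocol.spike_time + 100.0
        a = m_protocol.probe_at(t0)
        b = m_protocol.probe_at(t0)
        assert a.theta_v == b.theta_v  # noiseless bisection is exact

    def test_bisection_postcondition_brackets_transition(self, m_protocol):
        sample = m_protocol.probe_at(m_protocol.spike_time + 100.0)
        params = m_protocol.params
        state = m_protocol.state_at(sample.t0).as_array()
        background = np.full(2001, m_protocol.i_c)
        assert _spikes_from_shift(
            params.as_array(), state, sample.theta_v + 0.01, background, 0.025
        )
        assert not _spikes_from_shift(
            params.as_array(), state, sample.theta_v - 0.01, background, 0.025
        )

    def test_threshold_voltage_consistent_with_charge(self, m_protocol):
        s = m_protocol.probe_at(m_protocol.spike_time + 150.0)
        assert s.theta_v == pytest.approx(s.v_pre + s.q_min / m_protocol.params.c_m)


class TestThresholdCurves:
    def test_no_adaptation_threshold_plateaus_quickly(self):
        lags, theta = postspike_threshold_curve(
            no_adaptation_neuron(), -70.0, [50.0, 300.0]
        )
        assert abs(theta[0] - theta[1]) < 0.5

    def test_m_current_slows_threshold_decay(self, m_protocol):
        lags = np.array([200.0, 800.0])
        _, th_m = postspike_threshold_curve(
            m_neuron(g_m=0.1), -70.0, lags, protocol=m_protocol
        )
        _, th_no = postspike_threshold_curve(no_adaptation_neuron(), -70.0, lags)
        assert (th_m[0] - th_m[1]) > (th_no[0] - th_no[1])

    def test_lag_order_preserved(self, m_protocol):
        lags = [20.0, 60.0, 150.0]
        out_lags, theta = postspike_threshold_curve(
            m_neuron(g_m=0.1), -70.0, lags, protocol=m_protocol
        )
        np.testing.assert_array_equal(out_lags, lags)
        assert np.all(np.diff(theta) < 0)  # decaying toward the plateau


class TestSpikeTriggeredCurrents:
    def test_zero_conductance_gives_zero_eta(self):
        res = spike_triggered_current(no_adaptation_neuron(), "M", v_c=-70.0)
        assert np.max(np.abs(res.eta)) == 0.0

    def test_eta_m_tail_is_log_linear(self):
        res = spike_triggered_current(m_neuron(g_m=0.1), "M")
        mask = (res.t >= 10) & (res.t <= 300)
        x, y = res.t[mask], np.log(res.eta[mask])
        coef = np.polyfit(x, y, 1)
        r2 = 1 - np.sum((y - np.polyval(coef, x)) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.98

    def test_eta_ahp_peak_near_analytic_maximum(self):
        # argmax of e^{-t/tau_Ca} - e^{-t/tau_s}: ln(tau_Ca/tau_s) * product/diff
        p = ahp_neuron()
        res = spike_triggered_current(p, "AHP")
        mask = res.t >= 4.0
        t_peak = res.t[mask][np.argmax(res.eta[mask])]
        tau_ca, tau_s = p.tau_ca, p.tau_s_tilde
        analytic = np.log(tau_ca / tau_s) * tau_ca * tau_s / (tau_ca - tau_s)
        assert analytic == pytest.approx(92.4, abs=0.1)
        assert t_peak == pytest.approx(analytic, abs=15.0)

    def test_eta_m_amplitude_scales_with_conductance(self):
        amps = []
        for g in (0.05, 0.1, 0.2):
            p = m_neuron(g_m=g)
            amps.append(fit_eta(spike_triggered_current(p, "M"), p).amplitude)
        ratios = np.array(amps) / amps[0]
        np.testing.assert_allclose(ratios, [1.0, 2.0, 4.0], rtol=0.2)

    def test_eta_ahp_time_constant_follows_tau_ca(self):
        p1 = ahp_neuron()
        p2 = ahp_neuron().replace(tau_ca=2 * p1.tau_ca)
        f1 = fit_eta(spike_triggered_current(p1, "AHP"), p1, free_tau=True)
        f2 = fit_eta(spike_triggered_current(p2, "AHP"), p2, free_tau=True)
        assert f2.tau_slow[0] / f1.tau_slow[0] == pytest.approx(2.0, rel=0.1)

    def test_fit_recovers_synthetic_exponential(self):
        t = np.arange(0.0, 500.0, 0.25)
        res = SpikeTriggeredResult(
            ion="M", t=t, eta=0.37 * np.exp(-t / 150.0), v_bar=-70.0,
            baseline=0.0, spike_time=20.0,
        )
        fit = fit_eta(res, m_neuron(), free_tau=True)
        assert fit.amplitude == pytest.approx(0.37, rel=0.01)
        assert fit.tau_slow[0] == pytest.approx(150.0, rel=0.01)

    def test_invalid_ion_rejected(self):
        with pytest.raises(ValueError, match="ion"):
            spike_triggered_current(m_neuron(), "Na")


class TestThresholdVariation:
    def test_identical_parameters_give_zero(self):
        lags = np.array([30.0, 120.0])
        _, h = threshold_variation_h(m_neuron(g_m=0.1), m_neuron(g_m=0.1), -70.0, lags)
        np.testing.assert_allclose(h, 0.0, atol=1e-9)

    def test_differing_fast_parameters_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            threshold_variation_h(
                m_neuron(g_m=0.1), m_neuron(g_m=0.0).replace(g_na=45.0), -70.0, [50.0]
            )

    def test_h_m_is_single_exponential_in_tau_p(self):
        lags = np.array([20.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0])
        pm = m_neuron(g_m=0.1)
        _, h = threshold_variation_h(pm, no_adaptation_neuron(), -70.0, lags)
        fit = fit_h(lags, h, "M", pm, v_bar=-70.4)
        resid = h - fit.amplitude * np.exp(-lags / fit.tau_slow[0])
        r2 = 1 - np.sum(resid**2) / np.sum((h - h.mean()) ** 2)
        assert r2 > 0.95
        assert fit.amplitude > 0

    def test_extraction_commutes_with_conductance_zeroing(self):
        # h_M is first-order independent of a small background g_AHP
        lags = np.array([30.0, 80.0, 150.0, 300.0])
        _, h0 = threshold_variation_h(
            m_neuron(g_m=0.1), no_adaptation_neuron(), -70.0, lags
        )
        _, h1 = threshold_variation_h(
            m_neuron(g_m=0.1, g_ahp=0.02),
            no_adaptation_neuron(g_ahp=0.02),
            -70.0,
            lags,
        )
        np.testing.assert_allclose(h1, h0, rtol=0.1)


class TestScalingPredictor:
    def test_linear_in_conductance(self):
        a = alpha_scaling_predictor("M", m_neuron(g_m=0.1), -70.0, 0.08)
        b = alpha_scaling_predictor("M", m_neuron(g_m=0.2), -70.0, 0.08)
        assert b == pytest.approx(2 * a)

    def test_singular_ahp_time_constants_rejected(self):
        p = ahp_neuron().replace(tau_ca=50.0, beta_s=0.02)  # tau_s = 50 too
        with pytest.raises(ValueError, match="singular"):
            alpha_scaling_predictor("AHP", p, -70.0, 0.08)

    def test_predictor_correlates_with_measured_eta_amplitude(self):
        # scaling law vs directly fitted a_M over a small parameter grid
        preds, fits = [], []
        for g in (0.05, 0.2):
            for tau_max in (500.0, 2000.0):
                p = m_neuron(g_m=g, tau_max=tau_max)
                res = spike_triggered_current(p, "M")
                f = fit_eta(res, p)
                fits.append(f.amplitude)
                preds.append(
                    alpha_scaling_predictor("M", p, res.v_bar, res.delta_p)
                )
        r = np.corrcoef(preds, fits)[0, 1]
        assert r > 0.9
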