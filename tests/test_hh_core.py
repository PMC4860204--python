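"""Unit and property tests for the conductance-based neuron core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matreduce.exceptions import NotSubthresholdError, SimulationDivergedError
from matreduce.fixtures import (
    ahp_neuron,
    m_neuron,
    no_adaptation_neuron,
    rectangular_current,
)
from matreduce.hh_core import (
    ConductanceParams,
    NeuronState,
    SpikeTrain,
    Trace,
    detect_spikes,
    gate_rates,
    p_gate_steady,
    simulate,
    steady_state,
)


class TestGateRates:
    @pytest.mark.parametrize(
        "gate,v,expected_alpha",
        [
            ("m", -45.0, 1.28),  # removable singularity: 0.32 * 4
            ("n", -43.0, 0.16),  # 0.032 * 5
            ("q", -27.0, 0.209),  # 0.055 * 3.8
        ],
    )
    def test_singular_points_evaluate_to_limits(self, gate, v, expected_alpha):
        alpha, _ = gate_rates(gate, v)
        assert alpha == pytest.approx(expected_alpha, rel=1e-9)

    def test_beta_m_limit_at_minus_18(self):
        _, beta = gate_rates("m", -18.0)
        assert beta == pytest.approx(0.28 * 5.0, rel=1e-9)

    @pytest.mark.parametrize("gate,v0", [("m", -45.0), ("n", -43.0), ("q", -27.0)])
    def test_rates_continuous_across_singularity(self, gate, v0):
        a_mid, _ = gate_rates(gate, v0)
        for eps in (1e-8, -1e-8, 1e-5, -1e-5):
            a, _ = gate_rates(gate, v0 + eps)
            assert a == pytest.approx(a_mid, rel=1e-4)

    def test_p_gate_footnote_values(self):
        p_inf, tau_p = p_gate_steady(-35.0, tau_max_ms=1000.0)
        assert p_inf == pytest.approx(0.5)
        assert tau_p == pytest.approx(1000.0 / 4.3, rel=1e-12)

    def test_s_gate_rates_from_calcium(self):
        alpha, beta = gate_rates("s", v=-60.0, ca=0.05)
        assert alpha == pytest.approx(0.0005)
        assert beta == pytest.approx(0.02)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError, match="unknown gate"):
            gate_rates("z", -60.0)


class TestSteadyState:
    def test_leak_only_rests_at_e_l(self):
        p = ConductanceParams(g_na=0, g_kd=0, g_m=0, g_ca=0, g_ahp=0)
        st_ = steady_state(p, 0.0)
        assert st_.v == pytest.approx(p.e_l, abs=1e-5)

    def test_rest_s_gate_equilibrium(self, defaults, rest_state):
        # s_inf = alpha/(alpha+beta) at Ca ~ Ca_inf
        a, b = gate_rates("s", rest_state.v, rest_state.ca, defaults)
        assert rest_state.s == pytest.approx(a / (a + b), rel=1e-3)
        assert rest_state.s == pytest.approx(0.0244, abs=0.002)

    def test_rest_state_is_stationary(self, defaults, rest_state):
        tr = simulate(defaults, np.zeros(4000), init=rest_state)
        dv = np.diff(tr.v) / tr.dt
        assert np.max(np.abs(dv)) < 1e-6

    def test_suprathreshold_current_rejected(self, defaults):
        with pytest.raises(NotSubthresholdError):
            steady_state(defaults, 5.0)


class TestSimulate:
    def test_m_current_causes_spike_frequency_adaptation(self):
        # rectangular 3.2 uA/cm^2 into the g_M = 0.1 neuron
        stim = rectangular_current(3.2)
        sp = detect_spikes(simulate(m_neuron(g_m=0.1), stim))
        assert sp.n >= 4
        assert sp.isis[0] < sp.isis[-1]
        # firing slows down through the transient (tiny jitter tolerated)
        assert np.all(np.diff(sp.isis) >= -0.05)

    def test_no_adaptation_isis_constant(self):
        stim = rectangular_current(2.5)
        sp = detect_spikes(simulate(no_adaptation_neuron(), stim))
        tail = sp.isis[3:]
        assert np.ptp(tail) / tail.mean() < 0.05

    def test_ahp_neuron_adapts(self):
        stim = rectangular_current(3.1)
        sp = detect_spikes(simulate(ahp_neuron(), stim))
        assert sp.isis[0] < sp.isis[-1]

    def test_euler_step_convergence(self):
        # Euler phase error accumulates linearly in dt over a long adapting
        # train, so absolute spike times drift; spike count, onset latency
        # and the interval sequence are the dt-robust observables.
        stim_c = rectangular_current(3.2, dt=0.025)
        stim_f = rectangular_current(3.2, dt=0.01)
        sp_c = detect_spikes(simulate(m_neuron(g_m=0.1), stim_c, dt=0.025))
        sp_f = detect_spikes(simulate(m_neuron(g_m=0.1), stim_f, dt=0.01))
        assert sp_c.n == sp_f.n
        assert abs(sp_c.times[0] - sp_f.times[0]) < 0.5
        np.testing.assert_allclose(sp_c.isis, sp_f.isis, rtol=0.05)
        # the settled firing period agrees much more tightly
        assert abs(sp_c.isis[-1] - sp_f.isis[-1]) < 1.0

    def test_divergent_stimulus_reports_step(self, defaults, rest_state):
        stim = np.full(2000, 1e9)
        with pytest.raises(SimulationDivergedError, match="step"):
            simulate(defaults, stim, init=rest_state)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_gates_stay_bounded(self, seed):
        rng = np.random.default_rng(seed)
        # random piecewise-constant supra/subthreshold drive
        amps = rng.uniform(-2.0, 8.0, 10)
        stim = np.repeat(amps, 2000)  # 500 ms at dt = 0.025
        tr = simulate(
            m_neuron(), stim, init=steady_state(m_neuron(), 0.0), record_gates=True
        )
        gates = tr.gates[:, :7]
        assert gates.min() >= 0.0 and gates.max() <= 1.0

    def test_calcium_relaxes_with_tau_ca(self, defaults):
        # with g_Ca = 0 the Ca equation decouples: exponential decay to Ca_inf
        p = defaults.replace(g_ca=0.0)
        init = steady_state(p, 0.0)
        init = NeuronState(init.v, init.m, init.h, init.n, init.p, init.q, init.r,
                           init.s, ca=1.0)
        tr = simulate(p, np.zeros(int(400 / 0.025)), init=init, record_gates=True)
        ca = tr.gate("ca")
        y = np.log(ca - p.ca_inf)
        slope = np.polyfit(tr.t, y, 1)[0]
        assert -1.0 / slope == pytest.approx(p.tau_ca, rel=0.01)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        n = 1000
        tr = Trace(np.arange(n) * 0.025, np.full(n, -65.0), np.zeros(n), 0.025)
        assert detect_spikes(tr).n == 0

    def test_triangle_wave_crossings_interpolated(self):
        # triangle wave between -10 and +10 mV, period 40 ms
        dt = 0.025
        t = np.arange(int(120 / dt)) * dt
        v = 10.0 * (2 * np.abs((t / 40.0) % 1 - 0.5) - 0.5) * 2
        tr = Trace(t, v, np.zeros_like(t), dt)
        sp = detect_spikes(tr, level=0.0, debounce=2.0)
        # the rising branch crosses zero at t = 30 + 40 k (hand derivation)
        assert sp.n == 3
        np.testing.assert_allclose(sp.times, [30.0, 70.0, 110.0], atol=dt)

    def test_count_matches_local_maxima_oracle(self):
        stim = rectangular_current(3.2)
        tr = simulate(m_neuron(g_m=0.1), stim)
        v = tr.v
        peaks = np.sum((v[1:-1] > 0) & (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]))
        assert detect_spikes(tr).n == peaks

    def test_debounce_merges_double_crossings(self):
        dt = 0.025
        t = np.arange(400) * dt
        v = np.full_like(t, -65.0)
        for t0 in (2.0, 2.5, 8.0):  # two crossings 0.5 ms apart
            k = int(t0 / dt)
            v[k : k + 4] = 10.0
        tr = Trace(t, v, np.zeros_like(t), dt)
        assert detect_spikes(tr, debounce=2.0).n == 2


class TestTypes:
    def test_gate_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            NeuronState(-65, 1.2, 0, 0, 0, 0, 0, 0, 0.05)

    def test_spike_train_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrain(np.array([5.0, 3.0]), 10.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ConductanceParams(g_m=-0.1)
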