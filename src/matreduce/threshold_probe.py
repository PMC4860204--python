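"""Instantaneous spike threshold and spike-triggered kernel extraction.

The instantaneous spike threshold theta_V(t0) of the detailed model is the
minimal voltage from which an instantaneous shift at t0 elicits an action
potential.  It is located by bisection on the post-shift voltage over
[-80, 0] mV: each trial resets V to the candidate (gates and [Ca2+] are
left untouched) and watches 50 ms for a spike.

Built on top of the probe, this module extracts the two ingredients of the
reduced threshold kernel: the spike-triggered slow K+ currents eta_ion(t)
(deviation of I_M or I_AHP from its holding baseline after a single evoked
spike) and the spike-threshold variation h_ion(t) (threshold difference
between a neuron with and without the slow conductance), and fits both with
the closed exponential families

    eta_M, h_M     ~ e^{-t/tau_p(v_bar)}
    eta_AHP, h_AHP ~ e^{-t/tau_Ca} - e^{-t/tau_s},  tau_s = 1/beta_s.

Fast Na+/Kd/Ca transients decay within a few ms of spike onset, so the
analysis window starts 4 ms after the spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels as _k
from .exceptions import (
    BracketError,
    ContaminationError,
    FitFailureError,
)
from .hh_core import (
    DEFAULT_DT,
    ConductanceParams,
    NeuronState,
    Trace,
    detect_spikes,
    p_gate_steady,
    simulate,
    steady_state,
)
from .stimuli import PulseSpec, pulse_current, tune_holding_current

BISECTION_INTERVAL = (-80.0, 0.0)  # mV
BISECTION_TOL = 1e-4  # mV
PROBE_WINDOW = 50.0  # ms watched for a spike after the shift
ANALYSIS_WINDOW = (4.0, 500.0)  # ms after spike onset


@dataclass(frozen=True)
class ThresholdSample:
    """One probed threshold: theta_V = V(t0-0) + q_min / C_m."""

    t0: float  # ms
    theta_v: float  # mV
    q_min: float  # nC/cm^2
    v_pre: float  # mV, voltage immediately before the probe


@dataclass(frozen=True)
class KernelComponentFit:
    """Fitted exponential component of a spike-triggered series.

    ``amplitude`` is a_ion (uA/cm^2) for eta fits or b_ion (mV) for h fits;
    ``tau_slow`` is tau_p(v_bar) for the M component or the (tau_Ca, tau_s)
    pair for the AHP component.
    """

    ion: str  # "M" or "AHP"
    kind: str  # "eta" or "h"
    amplitude: float
    tau_slow: tuple  # (tau_p,) or (tau_ca, tau_s), ms
    v_bar: Optional[float]  # mV
    rms_residual: float
    delta_p: Optional[float] = None  # per-spike p-gate increment
    delta_ca: Optional[float] = None  # per-spike [Ca2+] increment, uM


def _spikes_from_shift(
    P: np.ndarray,
    state: np.ndarray,
    c: float,
    background: np.ndarray,
    dt: float,
) -> bool:
    """Does an instantaneous shift V -> c elicit a spike within the window?"""
    y = state.copy()
    y[0] = c
    V, _, _, status, _ = _k.integrate(P, background, dt, y, False, False)
    if status != _k.STATUS_OK:
        return True  # divergence past 0 mV counts as a spike
    return bool(np.max(V[1:]) > 0.0)


def instantaneous_threshold_from_state(
    params: ConductanceParams,
    state: NeuronState,
    background: np.ndarray,
    t0: float = 0.0,
    dt: float = DEFAULT_DT,
    interval: tuple = BISECTION_INTERVAL,
    tol: float = BISECTION_TOL,
) -> ThresholdSample:
    """Bisection threshold probe from an explicit pre-probe state.

    ``background`` is the external current over the post-probe watch window
    (at least ``PROBE_WINDOW`` ms).  Raises :class:`BracketError` when the
    interval does not bracket the spiking/non-spiking transition.
    """
    P = params.as_array()
    y = state.as_array()
    a, b = interval
    spikes_a = _spikes_from_shift(P, y, a, background, dt)
    spikes_b = _spikes_from_shift(P, y, b, background, dt)
    if spikes_a or not spikes_b:
        raise BracketError(
            f"threshold not bracketed in [{a}, {b}] mV "
            f"(lower end spikes: {spikes_a}, upper end spikes: {spikes_b})"
        )
    while b - a > tol:
        c = 0.5 * (a + b)
        if _spikes_from_shift(P, y, c, background, dt):
            b = c
        else:
            a = c
    theta = 0.5 * (a + b)
    return ThresholdSample(
        t0=t0,
        theta_v=theta,
        q_min=params.c_m * (theta - state.v),
        v_pre=state.v,
    )


@dataclass
class HoldingProtocol:
    """Holding-plus-pulse background used by all probe-based analyses.

    The neuron is held at ``v_c`` by a tuned constant current, a charge
    pulse at ``t_p`` shifts the voltage to -45 mV and evokes exactly one
    spike, and the trajectory (with gates and per-ion currents) is recorded
    for ``duration`` ms.
    """

    params: ConductanceParams
    v_c: float = -70.0
    t_p: float = 20.0
    duration: float = 600.0
    dt: float = DEFAULT_DT

    def __post_init__(self):
        self.i_c = tune_holding_current(self.params, self.v_c, dt=self.dt)
        self.init = steady_state(self.params, self.i_c, dt=self.dt)
        n = int(round(self.duration / self.dt))
        grid = np.arange(n) * self.dt
        spec = PulseSpec.to_spike_onset(self.params, self.i_c, self.init.v, self.t_p)
        self.stimulus = pulse_current(spec, grid)
        self.trace: Trace = simulate(
            self.params,
            self.stimulus,
            dt=self.dt,
            init=self.init,
            record_currents=True,
            record_gates=True,
        )
        spikes = detect_spikes(self.trace)
        if spikes.n == 0:
            raise BracketError("holding pulse failed to evoke a spike")
        self.spike_time = float(spikes.times[0])
        self.n_spikes = spikes.n

    def state_at(self, t: float) -> NeuronState:
        idx = int(round(t / self.dt))
        idx = min(idx, len(self.trace.t) - 1)
        return self.trace.state_at(idx)

    def probe_at(self, t0: float) -> ThresholdSample:
        """Instantaneous threshold at absolute time t0 of this protocol."""
        if t0 > self.duration:
            # beyond the recorded background: continue under the constant hold
            state = self.state_at(self.duration)
        else:
            state = self.state_at(t0)
        n_bg = int(round(PROBE_WINDOW / self.dt)) + 1
        background = np.full(n_bg, self.i_c)
        sample = instantaneous_threshold_from_state(
            self.params, state, background, t0=t0, dt=self.dt
        )
        return sample


def instantaneous_threshold(
    params: ConductanceParams,
    protocol: HoldingProtocol,
    t0: float,
) -> ThresholdSample:
    """Instantaneous spike threshold at time t0 of a holding protocol."""
    if protocol.params != params:
        raise ValueError("protocol was built for different parameters")
    return protocol.probe_at(t0)


def postspike_threshold_curve(
    params: ConductanceParams,
    v_c: float,
    lags: Sequence[float],
    dt: float = DEFAULT_DT,
    protocol: Optional[HoldingProtocol] = None,
) -> tuple:
    """Threshold theta_V(lag) at the given lags after a pulse-evoked spike.

    Returns (lags array, theta_V array).  Lags are measured from the spike
    onset (0 mV crossing).
    """
    lags = np.asarray(lags, dtype=float)
    if protocol is None:
        duration = max(600.0, 25.0 + float(lags.max()) + PROBE_WINDOW)
        protocol = HoldingProtocol(params, v_c=v_c, duration=duration, dt=dt)
    theta = np.array(
        [protocol.probe_at(protocol.spike_time + lag).theta_v for lag in lags]
    )
    return lags, theta


@dataclass(frozen=True)
class SpikeTriggeredResult:
    """eta_ion(t) after a single evoked spike, plus per-spike increments."""

    ion: str
    t: np.ndarray  # ms after spike onset
    eta: np.ndarray  # uA/cm^2
    v_bar: float  # mean voltage over the analysis window, mV
    baseline: float  # holding-level ionic current, uA/cm^2
    spike_time: float  # ms
    delta_p: Optional[float] = None
    delta_ca: Optional[float] = None


def spike_triggered_current(
    params: ConductanceParams,
    ion: str,
    v_c: float = -70.0,
    dt: float = DEFAULT_DT,
    window: tuple = ANALYSIS_WINDOW,
    protocol: Optional[HoldingProtocol] = None,
) -> SpikeTriggeredResult:
    """Spike-triggered slow K+ current eta_ion(t) = I_ion(t_sp + t) - baseline.

    Raises :class:`ContaminationError` if a second spike falls inside the
    analysis window.
    """
    if ion not in ("M", "AHP"):
        raise ValueError("ion must be 'M' or 'AHP'")
    if protocol is None:
        duration = 25.0 + window[1] + 50.0
        protocol = HoldingProtocol(params, v_c=v_c, duration=duration, dt=dt)
    if protocol.n_spikes > 1:
        raise ContaminationError(
            f"{protocol.n_spikes} spikes in the analysis window; expected one"
        )
    tr = protocol.trace
    name = "I_M" if ion == "M" else "I_AHP"
    series = tr.current(name)
    k_sp = int(round(protocol.spike_time / dt))
    k_pre = int(round((protocol.t_p - 1.0) / dt))  # 1 ms before the pulse
    baseline = float(series[k_pre])
    k_end = min(k_sp + int(round(window[1] / dt)), len(series) - 1)
    t_rel = (np.arange(k_sp, k_end + 1) - k_sp) * dt
    eta = series[k_sp : k_end + 1] - baseline
    mask = t_rel >= window[0]
    v_bar = float(tr.v[k_sp : k_end + 1][mask].mean())
    k4 = k_sp + int(round(window[0] / dt))
    delta_p = float(tr.gate("p")[k4] - tr.gate("p")[k_pre])
    delta_ca = float(tr.gate("ca")[k4] - tr.gate("ca")[k_pre])
    return SpikeTriggeredResult(
        ion=ion,
        t=t_rel,
        eta=eta,
        v_bar=v_bar,
        baseline=baseline,
        spike_time=protocol.spike_time,
        delta_p=delta_p,
        delta_ca=delta_ca,
    )


def _fit_single_exp(t, y, tau0, free_tau):
    if free_tau:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            y,
            p0=[max(y.max(), 1e-12), tau0],
            maxfev=10000,
        )
        a, tau = popt
        resid = y - a * np.exp(-t / tau)
    else:
        phi = np.exp(-t / tau0)
        a = float(np.dot(phi, y) / np.dot(phi, phi))
        tau = tau0
        resid = y - a * phi
    return a, tau, float(np.sqrt(np.mean(resid**2)))


def _fit_double_exp(t, y, tau_slow0, tau_fast, free_tau):
    if free_tau:
        popt, _ = curve_fit(
            lambda tt, a, tc: a * (np.exp(-tt / tc) - np.exp(-tt / tau_fast)),
            t,
            y,
            p0=[max(abs(y).max(), 1e-12), tau_slow0],
            maxfev=10000,
        )
        a, tau_slow = popt
        resid = y - a * (np.exp(-t / tau_slow) - np.exp(-t / tau_fast))
    else:
        phi = np.exp(-t / tau_slow0) - np.exp(-t / tau_fast)
        a = float(np.dot(phi, y) / np.dot(phi, phi))
        tau_slow = tau_slow0
        resid = y - a * phi
    return a, tau_slow, float(np.sqrt(np.mean(resid**2)))


def fit_eta(
    result: SpikeTriggeredResult,
    params: ConductanceParams,
    fixed_taus: Optional[tuple] = None,
    free_tau: bool = False,
    window: tuple = ANALYSIS_WINDOW,
) -> KernelComponentFit:
    """Least-squares fit of eta_ion with its closed exponential form.

    For the M current the time constant is tau_p evaluated at the mean
    post-spike voltage v_bar (or ``fixed_taus[0]``); for the AHP current the
    (tau_Ca, tau_s) pair comes from the biophysical parameters (or
    ``fixed_taus``).  ``free_tau`` additionally optimizes the slow time
    constant.  Raises :class:`FitFailureError` on a non-positive fitted
    time constant.
    """
    mask = (result.t >= window[0]) & (result.t <= window[1])
    t, y = result.t[mask], result.eta[mask]
    if result.ion == "M":
        if fixed_taus is not None:
            tau0 = fixed_taus[0]
        else:
            _, tau0 = p_gate_steady(result.v_bar, params.tau_max)
        a, tau, rms = _fit_single_exp(t, y, tau0, free_tau)
        taus = (float(tau),)
    else:
        if fixed_taus is not None:
            tau_ca, tau_s = fixed_taus
        else:
            tau_ca, tau_s = params.tau_ca, params.tau_s_tilde
        a, tau_ca_fit, rms = _fit_double_exp(t, y, tau_ca, tau_s, free_tau)
        taus = (float(tau_ca_fit), float(tau_s))
    if any(tau <= 0 for tau in taus):
        raise FitFailureError(f"fitted time constant(s) {taus} not positive")
    return KernelComponentFit(
        ion=result.ion,
        kind="eta",
        amplitude=float(a),
        tau_slow=taus,
        v_bar=result.v_bar,
        rms_residual=rms,
        delta_p=result.delta_p,
        delta_ca=result.delta_ca,
    )


def fit_h(
    lags: np.ndarray,
    h: np.ndarray,
    ion: str,
    params: ConductanceParams,
    v_bar: Optional[float] = None,
    free_tau: bool = False,
) -> KernelComponentFit:
    """Fit the threshold variation h_ion(lag) with the matching kernel form."""
    lags = np.asarray(lags, dtype=float)
    h = np.asarray(h, dtype=float)
    if ion == "M":
        if v_bar is None:
            raise ValueError("v_bar required to evaluate tau_p for the M fit")
        _, tau0 = p_gate_steady(v_bar, params.tau_max)
        a, tau, rms = _fit_single_exp(lags, h, tau0, free_tau)
        taus = (float(tau),)
    elif ion == "AHP":
        a, tau_ca, rms = _fit_double_exp(
            lags, h, params.tau_ca, params.tau_s_tilde, free_tau
        )
        taus = (float(tau_ca), params.tau_s_tilde)
    else:
        raise ValueError("ion must be 'M' or 'AHP'")
    if any(tau <= 0 for tau in taus):
        raise FitFailureError(f"fitted time constant(s) {taus} not positive")
    return KernelComponentFit(
        ion=ion, kind="h", amplitude=float(a), tau_slow=taus, v_bar=v_bar,
        rms_residual=rms,
    )


def threshold_variation_h(
    params_with: ConductanceParams,
    params_without: ConductanceParams,
    v_c: float,
    lags: Sequence[float],
    dt: float = DEFAULT_DT,
) -> tuple:
    """Spike-triggered threshold variation attributable to one slow current.

    h_ion(lag) = [theta_V^with(lag) - theta_V^with(rest)]
               - [theta_V^without(lag) - theta_V^without(rest)],

    where each neuron's resting threshold is probed at the holding steady
    state before the evoked spike.  Subtracting each neuron's own resting
    threshold removes the tonic contribution of the slow conductance (which
    belongs to theta_V_inf, not to the spike-triggered kernel).  The two
    parameter sets must differ only in the slow K+ conductances (g_M,
    g_AHP) so the difference isolates the slow current's effect.
    """
    fields = [f for f in ConductanceParams.__dataclass_fields__ if f not in
              ("g_m", "g_ahp")]
    for f in fields:
        if getattr(params_with, f) != getattr(params_without, f):
            raise ValueError(f"parameter sets differ in {f}, not only in g_M/g_AHP")
    lags = np.asarray(lags, dtype=float)
    curves = []
    for params in (params_with, params_without):
        duration = max(600.0, 25.0 + float(lags.max()) + PROBE_WINDOW)
        protocol = HoldingProtocol(params, v_c=v_c, duration=duration, dt=dt)
        rest_theta = protocol.probe_at(protocol.t_p - 5.0).theta_v
        _, theta = postspike_threshold_curve(params, v_c, lags, dt=dt,
                                             protocol=protocol)
        curves.append(theta - rest_theta)
    return lags, curves[0] - curves[1]


def spike_waveform_stats(protocol: HoldingProtocol, onset_level: float = -45.0) -> tuple:
    """(w_sp, delta_V): spike width and voltage change over the spike.

    The width is the time the voltage spends above ``onset_level`` (the
    pulse target, a proxy for the threshold at spike onset); delta_V is the
    voltage 1 ms after repolarization minus the onset voltage, typically a
    few to ~20 mV hyperpolarizing.  Both are measured, not assumed.
    """
    tr = protocol.trace
    dt = protocol.dt
    k0 = int(round(protocol.spike_time / dt))  # 0 mV upward crossing
    above = tr.v >= onset_level
    # walk out from the spike peak region to the bracketing onset-level
    # crossings (the pulse itself momentarily touches the onset level, so
    # the search is anchored at the 0 mV crossing, not the pulse)
    k_up = k0
    while k_up > 0 and above[k_up - 1]:
        k_up -= 1
    k_down = k0
    while k_down < len(above) - 1 and above[k_down]:
        k_down += 1
    w_sp = (k_down - k_up) * dt
    k_after = min(k_down + int(round(1.0 / dt)), len(tr.v) - 1)
    delta_v = float(tr.v[k_after] - tr.v[k_up])
    return w_sp, delta_v


def alpha_scaling_predictor(
    ion: str,
    params: ConductanceParams,
    v_bar: float,
    delta: float,
) -> float:
    """Unnormalized prediction of the slow kernel weight.

    M:   g_M (v_bar - E_K) delta_p / tau_max
    AHP: g_AHP (v_bar - E_K) delta_Ca tau_Ca tau_s / (tau_Ca - tau_s)

    Only scaling relations are meaningful (the proportionality constant is
    fitted numerically, not derived).
    """
    if ion == "M":
        return params.g_m * (v_bar - params.e_k) * delta / params.tau_max
    if ion == "AHP":
        tau_s = params.tau_s_tilde
        if params.tau_ca == tau_s:
            raise ValueError("tau_Ca equals tau_s; the AHP predictor is singular")
        return (
            params.g_ahp
            * (v_bar - params.e_k)
            * delta
            * params.tau_ca
            * tau_s
            / (params.tau_ca - tau_s)
        )
    raise ValueError("ion must be 'M' or 'AHP'")
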