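"""Single-compartment conductance-based neuron with slow K+ currents.

The membrane equation is

    C_m dV/dt = -I_L - I_Na - I_Kd - I_M - I_Ca - I_AHP + I_ex,

with Hodgkin-Huxley gating kinetics dw/dt = alpha_w (1-w) - beta_w w for
w in {m, h, n, p, q, r, s} and first-order intracellular Ca2+ dynamics

    d[Ca]/dt = -1e5 * I_Ca / (2 F) - ([Ca] - [Ca]_inf) / tau_Ca.

Spike-frequency adaptation is carried by the muscarinic K+ current
I_M = g_M p (V - E_K) (voltage-gated p, time constant up to seconds) and the
afterhyperpolarization current I_AHP = g_AHP s (V - E_K) whose s-gate is
activated by intracellular Ca2+.

All quantities use a single unit system: ms, mV, uA/cm^2, uF/cm^2, mS/cm^2,
uM.  Integration is forward Euler at a fixed step (default 0.025 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels as _k
from .exceptions import (
    ConvergenceError,
    NotSubthresholdError,
    SimulationDivergedError,
)

DEFAULT_DT = 0.025  # ms
DEFAULT_DEBOUNCE = 2.0  # ms; suppresses double-detection on one spike

GATE_NAMES = ("m", "h", "n", "p", "q", "r", "s")
CURRENT_NAMES = ("I_L", "I_Na", "I_Kd", "I_M", "I_Ca", "I_AHP")


@dataclass(frozen=True)
class ConductanceParams:
    """Biophysical constants of the detailed model.

    Defaults are the cortical regular-spiking parameter set with an M-type
    conductance of 0.1 mS/cm^2 and an AHP conductance of 0.2 mS/cm^2.  Note
    the internal time unit is ms throughout, so ``tau_max`` (the p-gate time
    scale, physiologically 0.5-4 s) defaults to 1000 ms and ``tau_ca`` (the
    Ca2+ relaxation constant, 100-900 ms) defaults to 200 ms.
    """

    c_m: float = 1.0  # uF/cm^2
    g_l: float = 0.1  # mS/cm^2
    g_na: float = 50.0
    g_kd: float = 5.0
    g_m: float = 0.1
    g_ca: float = 1e-3
    g_ahp: float = 0.2
    e_l: float = -80.0  # mV
    e_na: float = 50.0
    e_k: float = -90.0
    e_ca: float = 120.0
    tau_max: float = 1000.0  # ms
    beta_s: float = 0.02  # /ms (s-gate inactivation rate)
    tau_ca: float = 200.0  # ms
    ca_inf: float = 0.05  # uM
    faraday: float = 9.6485e4  # C/mol

    def __post_init__(self):
        for name in ("g_l", "g_na", "g_kd", "g_m", "g_ca", "g_ahp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("c_m", "tau_max", "beta_s", "tau_ca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.c_m,
                self.g_l,
                self.g_na,
                self.g_kd,
                self.g_m,
                self.g_ca,
                self.g_ahp,
                self.e_l,
                self.e_na,
                self.e_k,
                self.e_ca,
                self.tau_max,
                self.beta_s,
                self.tau_ca,
                self.ca_inf,
                self.faraday,
            ]
        )

    def replace(self, **kwargs) -> "ConductanceParams":
        return replace(self, **kwargs)

    @property
    def tau_s_tilde(self) -> float:
        """Approximate s-gate time constant 1/beta_s (ms)."""
        return 1.0 / self.beta_s


@dataclass
class NeuronState:
    """Instantaneous state: voltage, seven gates, and [Ca2+]."""

    v: float
    m: float
    h: float
    n: float
    p: float
    q: float
    r: float
    s: float
    ca: float

    def __post_init__(self):
        for g in GATE_NAMES:
            x = getattr(self, g)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {g} = {x} outside [0, 1]")
        if self.ca < 0:
            raise ValueError("Ca concentration must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v, self.m, self.h, self.n, self.p, self.q, self.r, self.s, self.ca]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        return cls(*[float(x) for x in y])


@dataclass
class Trace:
    """Uniformly sampled trajectory of the membrane voltage.

    ``currents`` (n x 6, columns ``CURRENT_NAMES``) and ``gates``
    (n x 8, columns m,h,n,p,q,r,s,Ca) are recorded on request.
    """

    t: np.ndarray  # ms
    v: np.ndarray  # mV
    i_ex: np.ndarray  # uA/cm^2
    dt: float
    currents: Optional[np.ndarray] = None
    gates: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.t)
        if len(self.v) != n or len(self.i_ex) != n:
            raise ValueError("t, v, i_ex must have equal length")

    @property
    def duration(self) -> float:
        return len(self.t) * self.dt

    def current(self, name: str) -> np.ndarray:
        if self.currents is None:
            raise ValueError("trace was recorded without per-ion currents")
        return self.currents[:, CURRENT_NAMES.index(name)]

    def gate(self, name: str) -> np.ndarray:
        if self.gates is None:
            raise ValueError("trace was recorded without gate series")
        cols = GATE_NAMES + ("ca",)
        return self.gates[:, cols.index(name)]

    def state_at(self, index: int) -> NeuronState:
        if self.gates is None:
            raise ValueError("state reconstruction requires gate recording")
        g = self.gates[index]
        return NeuronState(float(self.v[index]), *[float(x) for x in g])


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) over an observation window [0, duration)."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        return 1000.0 * self.n / self.duration

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def gate_rates(gate_id: str, v: float, ca: float = 0.05,
               params: Optional[ConductanceParams] = None):
    """Opening/closing rates (alpha, beta) in /ms for one gating variable.

    Rates with removable singularities (alpha_m at V = -45, alpha_n at -43,
    alpha_q at -27, beta_m at -18) are evaluated by their analytic limits.
    ``params`` supplies tau_max (p-gate) and beta_s (s-gate); package
    defaults are used when omitted.
    """
    if params is None:
        params = ConductanceParams()
    if gate_id == "m":
        return _k.rates_m(v)
    if gate_id == "h":
        return _k.rates_h(v)
    if gate_id == "n":
        return _k.rates_n(v)
    if gate_id == "p":
        return _k.rates_p(v, params.tau_max)
    if gate_id == "q":
        return _k.rates_q(v)
    if gate_id == "r":
        return _k.rates_r(v)
    if gate_id == "s":
        return _k.rates_s(ca, params.beta_s)
    raise ValueError(f"unknown gate id {gate_id!r}; expected one of m,h,n,p,q,r,s")


def p_gate_steady(v: float, tau_max_ms: float = 1000.0):
    """(p_inf, tau_p) of the M-current gate at voltage v."""
    return _k.p_gate_inf_tau(v, tau_max_ms)


def steady_state(
    params: ConductanceParams,
    i_c: float = 0.0,
    dt: float = DEFAULT_DT,
    max_ms: float = 30000.0,
    tol: float = 1e-9,
) -> NeuronState:
    """Relax the neuron under a constant current until all derivatives vanish.

    Raises :class:`NotSubthresholdError` if the neuron spikes during the
    relaxation (the constant current is suprathreshold) and
    :class:`ConvergenceError` if the state is still moving after ``max_ms``.
    """
    y, converged, spiked = _k.relax(params.as_array(), i_c, dt, max_ms, tol)
    if spiked:
        raise NotSubthresholdError(
            f"neuron spiked during relaxation at I_c = {i_c:.4f} uA/cm^2"
        )
    if not converged:
        raise ConvergenceError(
            f"steady state not reached within {max_ms} ms (tol = {tol})"
        )
    # clip numerically-tiny gate excursions before constructing the state
    y[1:8] = np.clip(y[1:8], 0.0, 1.0)
    return NeuronState.from_array(y)


def simulate(
    params: ConductanceParams,
    stimulus: np.ndarray,
    dt: float = DEFAULT_DT,
    init: Optional[NeuronState] = None,
    record_currents: bool = False,
    record_gates: bool = False,
) -> Trace:
    """Forward-Euler trajectory of the detailed model.

    ``stimulus`` is the external current (uA/cm^2) sampled on the grid
    t = k*dt; the initial state defaults to the steady state under the
    stimulus' first sample (which must then be subthreshold).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stimulus = np.ascontiguousarray(stimulus, dtype=float)
    if stimulus.ndim != 1 or stimulus.size == 0:
        raise ValueError("stimulus must be a non-empty 1-D series")
    if init is None:
        init = steady_state(params, float(stimulus[0]), dt=dt)
    V, cur, gates, status, bad = _k.integrate(
        params.as_array(), stimulus, dt, init.as_array(), record_currents, record_gates
    )
    if status == _k.STATUS_NONFINITE:
        raise SimulationDivergedError(bad, bad * dt)
    t = np.arange(stimulus.size) * dt
    return Trace(
        t=t,
        v=V,
        i_ex=stimulus,
        dt=dt,
        currents=cur if record_currents else None,
        gates=gates if record_gates else None,
    )


def detect_spikes(
    trace: Trace,
    level: float = 0.0,
    debounce: float = DEFAULT_DEBOUNCE,
) -> SpikeTrain:
    """Spike times as upward crossings of ``level`` (linear interpolation).

    Crossings closer than ``debounce`` ms to the previous accepted spike are
    discarded, so one action potential yields one spike time.
    """
    return spike_times_from_series(trace.t, trace.v, trace.dt, level, debounce)


def spike_times_from_series(
    t: np.ndarray,
    v: np.ndarray,
    dt: float,
    level: float = 0.0,
    debounce: float = DEFAULT_DEBOUNCE,
) -> SpikeTrain:
    if len(v) == 0:
        raise ValueError("empty trace")
    below = v[:-1] < level
    above = v[1:] >= level
    idx = np.nonzero(below & above)[0]
    duration = len(v) * dt
    if idx.size == 0:
        return SpikeTrain(np.empty(0), duration)
    frac = (level - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * dt
    if debounce > 0:
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= debounce:
                kept.append(s)
        times = np.array(kept)
    return SpikeTrain(times, duration)
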