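"""Input currents: constant-plus-pulse and Ornstein-Uhlenbeck drives.

Two stimulus classes are used throughout.  The pulse protocol
I_ex(t) = I_c + q_c * delta(t - t_p) holds the membrane at a target voltage
V_c with a tuned constant current and evokes exactly one spike with a brief
charge injection q_c = C_m (-45 - V_c).  The in-vivo-like drive is an
Ornstein-Uhlenbeck process with mean mu, stationary SD sigma, and
correlation time tau_syn (2 ms by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .exceptions import BracketError, NotSubthresholdError
from .hh_core import (
    DEFAULT_DT,
    ConductanceParams,
    NeuronState,
    detect_spikes,
    gate_rates,
    simulate,
    steady_state,
)


@dataclass(frozen=True)
class PulseSpec:
    """Constant current with a delta pulse at t_p.

    ``q_c`` is the pulse charge in nC/cm^2; a charge q_c delivered to a
    membrane of capacitance C_m [uF/cm^2] jumps the voltage by q_c / C_m mV.
    """

    i_c: float  # uA/cm^2
    q_c: float  # nC/cm^2
    t_p: float  # ms
    v_c: Optional[float] = None  # holding voltage the pulse departs from, mV

    @classmethod
    def to_spike_onset(
        cls,
        params: ConductanceParams,
        i_c: float,
        v_c: float,
        t_p: float,
        target: float = -45.0,
    ) -> "PulseSpec":
        """Pulse sized to shift the voltage from V_c up to ``target`` mV."""
        return cls(i_c=i_c, q_c=params.c_m * (target - v_c), t_p=t_p, v_c=v_c)


@dataclass(frozen=True)
class OUSpec:
    """Ornstein-Uhlenbeck current: dI = -(I - mu)/tau_syn dt + sqrt(2 sigma^2/tau_syn) dW."""

    mu: float  # uA/cm^2
    sigma: float  # uA/cm^2
    tau_syn: float = 2.0  # ms
    seed: int = 0
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")


def pulse_current(spec: PulseSpec, grid: np.ndarray) -> np.ndarray:
    """Realize the pulse stimulus on a uniform time grid.

    The delta pulse becomes a single sample of extra amplitude q_c / dt at
    the grid point nearest t_p, so the discretely integrated charge is
    exactly q_c (q_c is in nC/cm^2 = uA/cm^2 * ms, hence no unit factor).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid must have at least two points")
    dt = grid[1] - grid[0]
    if spec.t_p < grid[0] or spec.t_p > grid[-1]:
        raise ValueError(f"pulse time {spec.t_p} ms outside grid")
    series = np.full(grid.size, spec.i_c, dtype=float)
    k = int(round((spec.t_p - grid[0]) / dt))
    series[k] += spec.q_c / dt
    return series


def ou_current(spec: OUSpec, duration: float) -> np.ndarray:
    """Exactly-discretized OU sample path of length round(duration/dt).

    Uses the stationary AR(1) update
    I_{k+1} = mu + (I_k - mu) a + sigma sqrt(1 - a^2) xi_k with
    a = exp(-dt/tau_syn), initialized from the stationary law, so the sample
    statistics are unbiased at any dt.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / spec.dt))
    rng = np.random.default_rng(spec.seed)
    if spec.sigma == 0.0:
        return np.full(n, spec.mu)
    a = np.exp(-spec.dt / spec.tau_syn)
    e = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    e[0] = rng.standard_normal()  # stationary init
    x = lfilter([1.0], [1.0, -a], e)
    return spec.mu + spec.sigma * x


def holding_current_estimate(params: ConductanceParams, v_c: float) -> float:
    """Constant current for which (V = v_c, gates at equilibrium) is a fixed point.

    At the fixed point the external current must cancel the total ionic
    current evaluated with every gate at its steady value and [Ca2+] at its
    own fixed point under the clamped I_Ca.
    """
    gates = {}
    for g in ("m", "h", "n", "p", "q", "r"):
        a, b = gate_rates(g, v_c, params=params)
        gates[g] = a / (a + b)
    i_ca = params.g_ca * gates["q"] ** 2 * gates["r"] * (v_c - params.e_ca)
    ca = params.ca_inf - 1e5 * params.tau_ca * i_ca / (2.0 * params.faraday)
    a_s, b_s = gate_rates("s", v_c, ca, params)
    s = a_s / (a_s + b_s)
    total = (
        params.g_l * (v_c - params.e_l)
        + params.g_na * gates["m"] ** 3 * gates["h"] * (v_c - params.e_na)
        + params.g_kd * gates["n"] ** 4 * (v_c - params.e_k)
        + params.g_m * gates["p"] * (v_c - params.e_k)
        + i_ca
        + params.g_ahp * s * (v_c - params.e_k)
    )
    return total


def tune_holding_current(
    params: ConductanceParams,
    v_c: float,
    tol: float = 0.05,
    dt: float = DEFAULT_DT,
) -> float:
    """Constant current that holds the resting membrane at ``v_c``.

    The fixed-point current is computed in closed form from the gate
    equilibria and verified by relaxation; a short bisection refines it if
    the realized steady voltage misses ``v_c`` by more than ``tol`` mV.
    Raises :class:`NotSubthresholdError` when holding at v_c is impossible
    without spiking.
    """
    i_c = holding_current_estimate(params, v_c)
    st = steady_state(params, i_c, dt=dt)  # may raise NotSubthresholdError
    if abs(st.v - v_c) <= tol:
        return i_c
    # the fixed point at v_c is not the one relaxation reaches: either v_c is
    # on an unstable branch (unreachable without spiking) or the closed-form
    # estimate needs refinement; try a local bisection before giving up
    lo, hi = i_c - 1.0, i_c + 1.0
    f_lo = steady_state(params, lo, dt=dt).v - v_c
    f_hi = steady_state(params, hi, dt=dt).v - v_c
    if f_lo > 0 or f_hi < 0:
        raise NotSubthresholdError(
            f"V_c = {v_c} mV is not reachable as a stable subthreshold state "
            f"(relaxation at the fixed-point current settles at {st.v:.2f} mV)"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = steady_state(params, mid, dt=dt).v - v_c
        if abs(f_mid) <= tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise BracketError(f"holding-current bisection did not reach {tol} mV")


def firing_rate(
    params: ConductanceParams,
    stimulus: np.ndarray,
    dt: float = DEFAULT_DT,
    init: Optional[NeuronState] = None,
) -> float:
    """Mean firing rate (Hz) under an arbitrary stimulus, from rest by default."""
    if init is None:
        init = steady_state(params, 0.0, dt=dt)
    tr = simulate(params, stimulus, dt=dt, init=init)
    return detect_spikes(tr).rate_hz


def tune_mean_for_rate(
    params: ConductanceParams,
    target_rate: float,
    sigma_rule: str = "equal",
    duration: float = 20000.0,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    rel_tol: float = 0.1,
    max_iter: int = 25,
) -> float:
    """OU mean mu producing the target firing rate (Hz) by bisection.

    ``sigma_rule`` slaves the noise SD to the mean: "equal" (sigma = mu,
    moderately noisy) or "double" (sigma = 2 mu, highly noisy).  The search
    brackets the target by doubling mu, then bisects until the simulated
    rate is within ``rel_tol`` of target.  Raises :class:`BracketError`
    with diagnostics when no bracket exists (e.g. practically silent
    targets).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    factor = {"equal": 1.0, "double": 2.0}.get(sigma_rule)
    if factor is None:
        raise ValueError("sigma_rule must be 'equal' or 'double'")
    init = steady_state(params, 0.0, dt=dt)

    def rate(mu: float) -> float:
        spec = OUSpec(mu=mu, sigma=factor * mu, seed=seed, dt=dt)
        return firing_rate(params, ou_current(spec, duration), dt=dt, init=init)

    lo, r_lo = 0.0, 0.0
    hi = 1.0
    r_hi = rate(hi)
    tries = 0
    while r_hi < target_rate:
        lo, r_lo = hi, r_hi
        hi *= 2.0
        r_hi = rate(hi)
        tries += 1
        if tries > 6:
            raise BracketError(
                f"cannot bracket {target_rate} Hz: rate({hi:.2f}) = {r_hi:.3f} Hz "
                f"after {tries} doublings (duration {duration} ms, seed {seed})"
            )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rate(mid)
        if abs(r_mid - target_rate) <= rel_tol * target_rate:
            return mid
        if r_mid < target_rate:
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    raise BracketError(
        f"rate bisection did not converge to {target_rate} Hz within {max_iter} "
        f"iterations; bracket [{lo:.4f}, {hi:.4f}] with rates "
        f"[{r_lo:.3f}, {r_hi:.3f}] Hz"
    )
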