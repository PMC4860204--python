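"""Numba-compiled numerical cores.

Everything here works in a single consistent unit system: time in ms, voltage
in mV, current densities in uA/cm^2, capacitance in uF/cm^2, conductances in
mS/cm^2, Ca2+ concentration in uM, rates in /ms.

The biophysical parameter vector ``P`` has the fixed layout defined by the
``P_*`` index constants; :class:`matreduce.hh_core.ConductanceParams` is the
user-facing owner of that layout.
"""

import math

import numpy as np
from numba import njit

# Parameter vector layout (see ConductanceParams.as_array)
P_CM = 0
P_GL = 1
P_GNA = 2
P_GKD = 3
P_GM = 4
P_GCA = 5
P_GAHP = 6
P_EL = 7
P_ENA = 8
P_EK = 9
P_ECA = 10
P_TAUMAX = 11  # ms
P_BETAS = 12  # /ms
P_TAUCA = 13  # ms
P_CAINF = 14  # uM
P_FARADAY = 15  # C/mol

NPARAMS = 16

# State vector layout: V, m, h, n, p, q, r, s, Ca
NSTATE = 9

# Status codes returned by the integrator
STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def _expm1_ratio(x: float, k: float) -> float:
    """x / (1 - exp(-x/k)); removable singularity at x = 0 with limit k."""
    z = x / k
    if abs(z) < 1e-7:
        # series: x/(1-e^{-z k ... }) = k * z/(1-e^{-z}) ~ k (1 + z/2)
        return k * (1.0 + 0.5 * z)
    return x / (1.0 - math.exp(-z))


@njit(cache=True)
def _expm1_ratio_neg(x: float, k: float) -> float:
    """x / (exp(x/k) - 1); removable singularity at x = 0 with limit k."""
    z = x / k
    if abs(z) < 1e-7:
        return k * (1.0 - 0.5 * z)
    return x / (math.expm1(z))


@njit(cache=True)
def rates_m(v: float):
    a = 0.32 * _expm1_ratio(v + 45.0, 4.0)
    b = 0.28 * _expm1_ratio_neg(v + 18.0, 5.0)
    return a, b


@njit(cache=True)
def rates_h(v: float):
    a = 0.128 * math.exp(-(v + 41.0) / 18.0)
    b = 4.0 / (1.0 + math.exp(-(v + 18.0) / 5.0))
    return a, b


@njit(cache=True)
def rates_n(v: float):
    a = 0.032 * _expm1_ratio(v + 43.0, 5.0)
    b = 0.5 * math.exp(-(v + 48.0) / 40.0)
    return a, b


@njit(cache=True)
def p_gate_inf_tau(v: float, tau_max_ms: float):
    p_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    tau_p = tau_max_ms / (
        3.3 * math.exp((v + 35.0) / 20.0) + math.exp(-(v + 35.0) / 20.0)
    )
    return p_inf, tau_p


@njit(cache=True)
def rates_p(v: float, tau_max_ms: float):
    p_inf, tau_p = p_gate_inf_tau(v, tau_max_ms)
    return p_inf / tau_p, (1.0 - p_inf) / tau_p


@njit(cache=True)
def rates_q(v: float):
    a = 0.055 * _expm1_ratio(v + 27.0, 3.8)
    b = 0.94 * math.exp(-(v + 75.0) / 17.0)
    return a, b


@njit(cache=True)
def rates_r(v: float):
    a = 0.000457 * math.exp(-(v + 13.0) / 50.0)
    b = 0.0065 / (1.0 + math.exp(-(v + 15.0) / 28.0))
    return a, b


@njit(cache=True)
def rates_s(ca: float, beta_s: float):
    return 0.01 * ca, beta_s


@njit(cache=True)
def ionic_currents(P, y, out):
    """Fill ``out[:6]`` with I_L, I_Na, I_Kd, I_M, I_Ca, I_AHP (uA/cm^2)."""
    v = y[0]
    out[0] = P[P_GL] * (v - P[P_EL])
    out[1] = P[P_GNA] * y[1] ** 3 * y[2] * (v - P[P_ENA])
    out[2] = P[P_GKD] * y[3] ** 4 * (v - P[P_EK])
    out[3] = P[P_GM] * y[4] * (v - P[P_EK])
    out[4] = P[P_GCA] * y[5] ** 2 * y[6] * (v - P[P_ECA])
    out[5] = P[P_GAHP] * y[7] * (v - P[P_EK])


@njit(cache=True)
def derivatives(P, y, i_ex, dy, cur):
    """Time derivative of the full state; also fills the current buffer."""
    ionic_currents(P, y, cur)
    total = cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
    dy[0] = (-total + i_ex) / P[P_CM]

    v = y[0]
    a, b = rates_m(v)
    dy[1] = a * (1.0 - y[1]) - b * y[1]
    a, b = rates_h(v)
    dy[2] = a * (1.0 - y[2]) - b * y[2]
    a, b = rates_n(v)
    dy[3] = a * (1.0 - y[3]) - b * y[3]
    a, b = rates_p(v, P[P_TAUMAX])
    dy[4] = a * (1.0 - y[4]) - b * y[4]
    a, b = rates_q(v)
    dy[5] = a * (1.0 - y[5]) - b * y[5]
    a, b = rates_r(v)
    dy[6] = a * (1.0 - y[6]) - b * y[6]
    a, b = rates_s(y[8], P[P_BETAS])
    dy[7] = a * (1.0 - y[7]) - b * y[7]
    # Ca2+ influx through I_Ca (inward => negative current => influx) plus
    # first-order relaxation toward the equilibrium concentration.
    dy[8] = -1.0e5 * cur[4] / (2.0 * P[P_FARADAY]) - (y[8] - P[P_CAINF]) / P[P_TAUCA]


@njit(cache=True)
def integrate(P, i_ex, dt, y0, record_currents, record_gates):
    """Forward-Euler trajectory.

    Returns (V, currents, gates, status, bad_step).  ``V[k]`` is the state at
    t = k*dt with ``V[0] = y0``; the k-th stimulus sample drives the step
    from k to k+1.  ``currents`` is (n, 6) and ``gates`` is (n, 8)
    [m,h,n,p,q,r,s,Ca] when requested, else (0, .)-shaped placeholders.
    """
    n = i_ex.size
    V = np.empty(n)
    cur_rec = np.empty((n if record_currents else 0, 6))
    gate_rec = np.empty((n if record_gates else 0, 8))
    y = y0.copy()
    dy = np.empty(NSTATE)
    cur = np.empty(6)
    status = STATUS_OK
    bad = -1
    for k in range(n):
        V[k] = y[0]
        # guard before evaluating rates: far outside the physiological range
        # the exponentials overflow and the trajectory has already diverged
        if not math.isfinite(y[0]) or abs(y[0]) > 1e3:
            status = STATUS_NONFINITE
            bad = k
            break
        derivatives(P, y, i_ex[k], dy, cur)
        if record_currents:
            for j in range(6):
                cur_rec[k, j] = cur[j]
        if record_gates:
            for j in range(8):
                gate_rec[k, j] = y[1 + j]
        if k < n - 1:
            for j in range(NSTATE):
                y[j] += dt * dy[j]
            # gate boundedness: forward Euler can step a gate marginally
            # outside [0,1]; clamp (excursions are O(1e-12) at dt = 0.025)
            for j in range(1, 8):
                if y[j] < 0.0:
                    y[j] = 0.0
                elif y[j] > 1.0:
                    y[j] = 1.0
            if y[8] < 0.0:
                y[8] = 0.0
    return V, cur_rec, gate_rec, status, bad


@njit(cache=True)
def relax(P, i_c, dt, max_ms, tol):
    """Integrate under constant current until the state stops moving.

    Returns (y, converged, spiked).  ``spiked`` is set when V crosses 0 mV
    upward at any point, in which case relaxation aborts.
    """
    y = np.empty(NSTATE)
    v0 = P[P_EL]
    y[0] = v0
    a, b = rates_m(v0)
    y[1] = a / (a + b)
    a, b = rates_h(v0)
    y[2] = a / (a + b)
    a, b = rates_n(v0)
    y[3] = a / (a + b)
    a, b = rates_p(v0, P[P_TAUMAX])
    y[4] = a / (a + b)
    a, b = rates_q(v0)
    y[5] = a / (a + b)
    a, b = rates_r(v0)
    y[6] = a / (a + b)
    y[8] = P[P_CAINF]
    a, b = rates_s(y[8], P[P_BETAS])
    y[7] = a / (a + b)

    dy = np.empty(NSTATE)
    cur = np.empty(6)
    nsteps = int(max_ms / dt)
    check_every = 2000
    v_prev = y[0]
    for k in range(nsteps):
        derivatives(P, y, i_c, dy, cur)
        for j in range(NSTATE):
            y[j] += dt * dy[j]
        for j in range(1, 8):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if y[8] < 0.0:
            y[8] = 0.0
        if v_prev < 0.0 <= y[0]:
            return y, False, True
        v_prev = y[0]
        if k % check_every == 0 and k > 0:
            derivatives(P, y, i_c, dy, cur)
            m = 0.0
            for j in range(NSTATE):
                if abs(dy[j]) > m:
                    m = abs(dy[j])
            if m < tol:
                return y, True, False
    derivatives(P, y, i_c, dy, cur)
    m = 0.0
    for j in range(NSTATE):
        if abs(dy[j]) > m:
            m = abs(dy[j])
    return y, m < tol, False


@njit(cache=True)
def mat_core(i_ex, dt, tau_m, c_m, theta_inf, amps, taus, refractory, record):
    """Exact-integration MAT simulation.

    The membrane potential u is advanced with the exact exponential update of
    the leaky integrator (the stimulus is held constant across each step);
    each threshold kernel exponential is a decaying accumulator incremented
    by its weight at every spike.  A spike is emitted at the first grid point
    with u >= theta outside the refractory period; u is never reset.

    Returns (spike_step_indices, u_series, theta_series); the series are
    empty unless ``record``.
    """
    n = i_ex.size
    a = math.exp(-dt / tau_m)
    b = tau_m * (1.0 - a) / c_m
    nk = amps.size
    dec = np.empty(nk)
    for j in range(nk):
        dec[j] = math.exp(-dt / taus[j])
    acc = np.zeros(nk)
    u = 0.0
    last_spike = -1.0e18
    spikes = np.empty(n, dtype=np.int64)
    ns = 0
    u_rec = np.empty(n if record else 0)
    th_rec = np.empty(n if record else 0)
    for k in range(n):
        theta = theta_inf
        for j in range(nk):
            theta += acc[j]
        if record:
            u_rec[k] = u
            th_rec[k] = theta
        t = k * dt
        if u >= theta and t - last_spike >= refractory:
            spikes[ns] = k
            ns += 1
            last_spike = t
            for j in range(nk):
                acc[j] += amps[j]
        u = u * a + i_ex[k] * b
        for j in range(nk):
            acc[j] *= dec[j]
    return spikes[:ns], u_rec, th_rec
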