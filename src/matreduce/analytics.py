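"""Analytic coding properties of the reduced model.

Under a constant suprathreshold current I_0 the MAT neuron settles onto a
periodic orbit with period T.  The threshold between spikes is the
geometric-series sum of the kernel over the infinite periodic spike history,

    eta_T_inf(t) = sum_j alpha_j e^{-t/tau_j} / (1 - e^{-T/tau_j}),

and the period solves theta_inf + eta_T_inf(T) = I_0 tau_m.  Without slow
terms this inverts in closed form to the LIF-like f-I curve
f = 1 / (tau_m log(1 + alpha_0 / (I_0 tau_m - theta_inf))).

A small potential perturbation delta_u shifts the next spike by
delta_T = delta_u / (d eta_T_inf/dt)(T); the relative dispersion
|delta_T|/T measures the sensitivity of the firing pattern to input noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import BracketError, SingularSensitivityError
from .mat_model import MATParams, ThresholdKernel


@dataclass(frozen=True)
class PeriodicSolution:
    i_0: float  # uA/cm^2
    period: float  # ms (inf when subthreshold)
    f_hz: float  # 1000/period, 0 when subthreshold
    residual: float  # |theta_inf + eta_T_inf(T) - I_0 tau_m| at the root


@dataclass(frozen=True)
class NoiseSensitivity:
    delta_u: float  # mV
    delta_t: float  # ms, signed; negative: upward u-perturbations advance spikes
    delta_t_over_t: float  # |delta_t| / T
    slope: float  # d eta_T_inf/dt at t = T, mV/ms; < 0 on a stable orbit


def eta_T_inf(kernel: ThresholdKernel, T: float, t):
    """Periodic threshold variation between spikes (mV).

    Equals the sum of H_u(t + k T) over all past periods k >= 0; each
    exponential sums as a geometric series.  As T -> inf the denominators
    tend to 1 and the function reduces to H_u(t).
    """
    if T <= 0:
        raise ValueError("period T must be > 0")
    amps, taus = kernel.terms()
    t_arr = np.asarray(t, dtype=float)
    denom = 1.0 - np.exp(-T / taus)
    vals = (amps / denom * np.exp(-t_arr[..., None] / taus)).sum(axis=-1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(vals)
    return vals


def eta_T_inf_slope(kernel: ThresholdKernel, T: float, t):
    """Time derivative d eta_T_inf/dt (mV/ms)."""
    if T <= 0:
        raise ValueError("period T must be > 0")
    amps, taus = kernel.terms()
    t_arr = np.asarray(t, dtype=float)
    denom = 1.0 - np.exp(-T / taus)
    vals = (-amps / (taus * denom) * np.exp(-t_arr[..., None] / taus)).sum(axis=-1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(vals)
    return vals


def fi_closed_form(theta_inf: float, alpha_0: float, tau_m: float, i_0: float) -> float:
    """Firing rate (Hz) of the adaptation-free reduced neuron.

    f = 0 for subthreshold drive (I_0 tau_m <= theta_inf).  Diverges as
    alpha_0 -> 0+ at fixed suprathreshold I_0 (no post-spike threshold
    increment means immediate re-crossing); callers should treat alpha_0 = 0
    as a domain edge.
    """
    drive = i_0 * tau_m - theta_inf
    if drive <= 0:
        return 0.0
    T = tau_m * np.log1p(alpha_0 / drive)
    if T <= 0:
        return np.inf
    return 1000.0 / T


def _period_residual(mat: MATParams, i_0: float, T: float) -> float:
    return mat.theta_inf + eta_T_inf(mat.kernel, T, T) - i_0 * mat.tau_m


def fi_adaptive(
    mat: MATParams,
    i_0: float,
    t_min: float = 0.1,
    t_max: float = 1e5,
    n_scan: int = 600,
) -> PeriodicSolution:
    """Asymptotic period/rate of the MAT neuron under constant current.

    Solves theta_inf + eta_T_inf(T) = I_0 tau_m by a log-spaced bracket scan
    followed by Brent root-finding.  When the AHP pair makes eta_T_inf(T)
    non-monotone there can be multiple roots; the smallest root with
    negative threshold slope (the attracting periodic orbit) is returned.
    Subthreshold drive gives a no-solution result (f = 0), not an exception.
    """
    if i_0 * mat.tau_m <= mat.theta_inf:
        return PeriodicSolution(i_0, np.inf, 0.0, 0.0)
    grid = np.geomspace(t_min, t_max, n_scan)
    res = np.array([_period_residual(mat, i_0, T) for T in grid])
    roots = []
    for a, b, ra, rb in zip(grid[:-1], grid[1:], res[:-1], res[1:]):
        if ra == 0.0:
            roots.append(a)
        elif ra * rb < 0:
            roots.append(brentq(lambda T: _period_residual(mat, i_0, T), a, b,
                                xtol=1e-10, rtol=1e-14))
    stable = [T for T in roots if eta_T_inf_slope(mat.kernel, T, T) < 0]
    if not stable:
        raise BracketError(
            f"no stable periodic solution found for I_0 = {i_0} "
            f"(scanned T in [{t_min}, {t_max}] ms, {len(roots)} roots)"
        )
    T = min(stable)
    return PeriodicSolution(i_0, T, 1000.0 / T, abs(_period_residual(mat, i_0, T)))


def noise_sensitivity(mat: MATParams, i_0: float, delta_u: float = 1.0) -> NoiseSensitivity:
    """Relative spike-interval dispersion |delta_T|/T under a small perturbation.

    Requires a stable periodic solution at I_0; raises
    :class:`SingularSensitivityError` when the threshold slope at the spike
    time vanishes.
    """
    sol = fi_adaptive(mat, i_0)
    if not np.isfinite(sol.period):
        raise BracketError(f"no periodic solution at I_0 = {i_0} (subthreshold)")
    slope = eta_T_inf_slope(mat.kernel, sol.period, sol.period)
    if slope == 0.0 or not np.isfinite(slope):
        raise SingularSensitivityError(
            f"threshold slope vanishes at T = {sol.period:.3f} ms"
        )
    delta_t = delta_u / slope
    return NoiseSensitivity(delta_u, delta_t, abs(delta_t) / sol.period, slope)


def current_for_rate(
    mat: MATParams,
    f_hz: float,
    i_max: float = 1e3,
) -> float:
    """Constant current producing the target asymptotic rate (bisection on I_0)."""
    if f_hz <= 0:
        raise ValueError("target rate must be > 0")
    lo = mat.theta_inf / mat.tau_m
    hi = lo + 1.0
    while fi_adaptive(mat, hi).f_hz < f_hz:
        hi = lo + 2 * (hi - lo)
        if hi > i_max:
            raise BracketError(f"cannot reach {f_hz} Hz below I_0 = {i_max}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fi_adaptive(mat, mid).f_hz < f_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
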