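"""Multi-timescale adaptive threshold (MAT) model.

The reduced neuron is a non-resetting leaky integrator

    du/dt = -u/tau_m + I_ex/C_m,

that emits a spike whenever u reaches the adaptive threshold

    theta_u(t) = theta_inf + sum_k H_u(t - t_k),

where the sum runs over past spike times t_k.  The threshold kernel is a
sum of exponentials: a fast term with the membrane time constant, an M-type
slow term with the p-gate time constant tau_p(v_bar), and an AHP
double-exponential pair (tau_Ca, tau_s) that vanishes at t = 0 and produces
a delayed hump.  u is never reset; adaptation lives entirely in the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from ._kernels import mat_core
from .hh_core import SpikeTrain


@dataclass(frozen=True)
class ThresholdKernel:
    """Post-spike threshold kernel H_u(t) (mV), zero for t <= 0.

    H_u(t) = alpha_0 e^{-t/tau_fast} + alpha_m e^{-t/tau_p}
             + alpha_ahp (e^{-t/tau_ca} - e^{-t/tau_s}).
    """

    alpha_0: float  # mV
    tau_fast: float = 10.0  # ms, the membrane time constant
    alpha_m: float = 0.0  # mV
    tau_p: float = 150.0  # ms, M-gate time constant at the mean voltage
    alpha_ahp: float = 0.0  # mV
    tau_ca: float = 200.0  # ms
    tau_s: float = 50.0  # ms, approximate s-gate time constant 1/beta_s

    def __post_init__(self):
        for name in ("tau_fast", "tau_p", "tau_ca", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_ahp != 0.0 and self.tau_ca == self.tau_s:
            raise ValueError("tau_ca must differ from tau_s when alpha_ahp != 0")

    def terms(self) -> Tuple[np.ndarray, np.ndarray]:
        """Signed exponential decomposition: (weights mV, time constants ms)."""
        amps = np.array([self.alpha_0, self.alpha_m, self.alpha_ahp, -self.alpha_ahp])
        taus = np.array([self.tau_fast, self.tau_p, self.tau_ca, self.tau_s])
        return amps, taus

    def __call__(self, t) -> np.ndarray:
        return threshold_kernel_eval(self, t)


def threshold_kernel_eval(kernel: ThresholdKernel, t):
    """Evaluate H_u(t); exactly zero for t <= 0 (scalar or array t)."""
    t_arr = np.asarray(t, dtype=float)
    amps, taus = kernel.terms()
    with np.errstate(over="ignore"):
        vals = np.where(
            t_arr[..., None] > 0, amps * np.exp(-t_arr[..., None] / taus), 0.0
        ).sum(axis=-1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(vals)
    return vals


@dataclass(frozen=True)
class MATParams:
    """Full parameter set of the reduced model."""

    theta_inf: float  # mV, resting threshold
    kernel: ThresholdKernel
    tau_m: float = 10.0  # ms
    c_m: float = 1.0  # uF/cm^2
    refractory: float = 2.0  # ms; prevents grid-step re-crossing (u not reset)

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def replace(self, **kwargs) -> "MATParams":
        return replace(self, **kwargs)


def simulate_mat(
    params: MATParams,
    stimulus: np.ndarray,
    dt: float = 0.025,
    record: bool = False,
) -> Tuple[SpikeTrain, Optional[np.ndarray], Optional[np.ndarray]]:
    """Simulate the MAT model under a current series.

    Subthreshold integration is exact (exponential update with the stimulus
    held constant over each step); only the threshold-crossing detection is
    grid-resolved, and spike times are reported at the grid point of the
    first u >= theta_u.  Returns (spikes, u series, theta series); the
    series are ``None`` unless ``record``.
    """
    stimulus = np.ascontiguousarray(stimulus, dtype=float)
    if not np.all(np.isfinite(stimulus)):
        raise ValueError("stimulus contains non-finite values")
    amps, taus = params.kernel.terms()
    idx, u, th = mat_core(
        stimulus,
        dt,
        params.tau_m,
        params.c_m,
        params.theta_inf,
        amps,
        taus,
        params.refractory,
        record,
    )
    train = SpikeTrain(idx * dt, stimulus.size * dt)
    if record:
        return train, u, th
    return train, None, None
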