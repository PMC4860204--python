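"""Fitting the reduced model to detailed-model data.

The structural parameters of the MAT model are fixed from biophysics
(C_m = 1 uF/cm^2, tau_m = 10 ms from the leak conductance, tau_Ca = 200 ms,
tau_s = 1/beta_s = 50 ms, and tau_p evaluated at the mean subthreshold
voltage of the training trace).  The remaining threshold parameters
{theta_inf, alpha_0, alpha_M or alpha_AHP} are found by maximizing the
coincidence factor Gamma between the detailed model's spike train and the
reduced model's prediction, using Nelder-Mead with seeded restarts (Gamma is
piecewise constant in the parameters, so the simplex walks a noisy plateau;
restarts are the mitigation).

``assemble_theory_kernel`` builds the kernel bottom-up instead: from the
spike waveform statistics (w_sp, delta_V) and the fitted eta/h components,
evaluating the exact effective kernel

    H(t) = -delta_V e^{-(t - w_sp)/tau_m}
           + C_m^{-1} sum_ion (eta_ion * e^{-t/tau_m})(t)
           + sum_ion h_ion(t)

(the convolution has a closed form for exponential eta) and projecting it
onto the MAT kernel family by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .evaluation import coincidence_factor
from .exceptions import UnfittableError
from .hh_core import ConductanceParams, SpikeTrain, p_gate_steady
from .mat_model import MATParams, ThresholdKernel, simulate_mat

DEFAULT_FIXED = {
    "c_m": 1.0,
    "tau_m": 10.0,
    "tau_ca": 200.0,
    "tau_s_tilde": 50.0,
    "tau_p_vbar": None,  # computed from the training trace, else 150 ms
}


@dataclass
class ReductionConfig:
    """Optimizer settings for the Gamma-maximization fit."""

    free: Tuple[str, ...] = ("theta_inf", "alpha_0", "alpha_m")
    fixed: dict = field(default_factory=lambda: dict(DEFAULT_FIXED))
    gamma_delta: float = 4.0  # ms
    restarts: int = 5
    max_iter: int = 250
    init: Tuple[float, float, float] = (30.0, 35.0, 3.0)
    init_scale: float = 0.5
    seed: int = 0
    refractory: float = 2.0

    def __post_init__(self):
        allowed = {"theta_inf", "alpha_0", "alpha_m", "alpha_ahp"}
        extra = set(self.free) - allowed
        if extra:
            raise ValueError(f"unknown free parameters {extra}")
        if self.gamma_delta <= 0:
            raise ValueError("gamma_delta must be > 0")


@dataclass
class ReductionResult:
    mat: MATParams
    gamma_train: float
    gamma_test: Optional[float] = None
    tau_p: Optional[float] = None
    restart_gammas: Optional[np.ndarray] = None  # best-so-far per restart


def subthreshold_vbar(v: np.ndarray, cutoff: float = -40.0) -> float:
    """Mean voltage over subthreshold samples (spike waveforms excluded)."""
    sub = v[v < cutoff]
    if sub.size == 0:
        return float(v.mean())
    return float(sub.mean())


def _build_mat(x: np.ndarray, config: ReductionConfig, tau_p: float) -> MATParams:
    vals = dict(zip(config.free, x))
    kernel = ThresholdKernel(
        alpha_0=vals.get("alpha_0", 0.0),
        tau_fast=config.fixed["tau_m"],
        alpha_m=vals.get("alpha_m", 0.0),
        tau_p=tau_p,
        alpha_ahp=vals.get("alpha_ahp", 0.0),
        tau_ca=config.fixed["tau_ca"],
        tau_s=config.fixed["tau_s_tilde"],
    )
    return MATParams(
        theta_inf=vals.get("theta_inf", 0.0),
        kernel=kernel,
        tau_m=config.fixed["tau_m"],
        c_m=config.fixed["c_m"],
        refractory=config.refractory,
    )


def _nelder_mead(objective, x0, scales, max_iter):
    return minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": 0.005,
            "fatol": 1e-9,
            "initial_simplex": x0 + np.vstack([np.zeros(x0.size), np.diag(scales)]),
        },
    )


def _optimize_gamma(neg_gamma, config: ReductionConfig):
    """Maximize Gamma over the free threshold parameters.

    Gamma is piecewise constant, so a plain simplex stalls on plateaus and
    curved (theta_inf, alpha_slow) valleys.  The search therefore proceeds
    in stages: a coarse grid around the initial guess, a chain of
    Nelder-Mead runs re-expanded from the incumbent, seeded jittered
    restarts, and a final per-coordinate refinement.  Returns
    (best_x, best_gamma, best-so-far trajectory across restarts).
    """
    rng = np.random.default_rng(config.seed)
    init = np.asarray(config.init, dtype=float)[: len(config.free)]
    ndim = init.size
    # stage 1: coarse grid (theta_inf +-6, alpha_0 +-10, slow weight 0..2x)
    axes = []
    for name, x0 in zip(config.free, init):
        if name == "theta_inf":
            axes.append(np.linspace(x0 - 6, x0 + 6, 7))
        elif name == "alpha_0":
            axes.append(np.linspace(x0 - 10, x0 + 10, 5))
        else:
            axes.append(np.linspace(0.0, max(2 * x0, 6.0), 5))
    best_x, best_f = init.copy(), neg_gamma(init)
    for point in np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, ndim):
        f = neg_gamma(point)
        if f < best_f:
            best_f, best_x = f, point.copy()
    scales = np.array([1.5, 2.0, 0.5][:ndim])
    # stage 2: chained simplex runs, re-expanding from the incumbent
    x = best_x.copy()
    for _ in range(4):
        res = _nelder_mead(neg_gamma, x, scales, config.max_iter)
        improved = res.fun < best_f - 1e-12
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
        x = res.x
        if not improved:
            break
    # stage 3: seeded jittered restarts
    best_so_far = [-best_f]
    for _ in range(max(config.restarts - 1, 0)):
        x0 = best_x + rng.normal(0.0, config.init_scale * scales)
        res = _nelder_mead(neg_gamma, x0, scales, config.max_iter)
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
        best_so_far.append(-best_f)
    # stage 4: per-coordinate refinement (two sweeps)
    spans = np.array([0.5, 2.0, 0.4][:ndim])
    for _ in range(2):
        for j in range(ndim):
            grid_j = best_x[j] + np.linspace(-spans[j], spans[j], 17)
            for val in grid_j:
                trial = best_x.copy()
                trial[j] = val
                f = neg_gamma(trial)
                if f < best_f:
                    best_f, best_x = f, trial
    best_so_far.append(-best_f)
    return best_x, -best_f, np.array(best_so_far)


def fit_mat(
    training: Tuple[np.ndarray, SpikeTrain],
    config: Optional[ReductionConfig] = None,
    dt: float = 0.025,
    v_trace: Optional[np.ndarray] = None,
    test: Optional[Tuple[np.ndarray, SpikeTrain]] = None,
) -> ReductionResult:
    """Fit the threshold parameters by coincidence-factor maximization.

    ``training`` is (current series, detailed-model spike train) on one
    grid; ``v_trace`` (the detailed voltage) supplies the mean subthreshold
    voltage from which tau_p is evaluated (150 ms is used when absent).
    ``test`` is an optional held-out pair evaluated with the fitted model.
    """
    if config is None:
        config = ReductionConfig()
    current, ref = training
    if ref.n == 0:
        raise UnfittableError("training spike train is empty")
    tau_p = config.fixed.get("tau_p_vbar")
    if tau_p is None:
        if v_trace is not None:
            _, tau_p = p_gate_steady(subthreshold_vbar(v_trace), 1000.0)
        else:
            tau_p = 150.0

    def neg_gamma(x: np.ndarray) -> float:
        mat = _build_mat(x, config, tau_p)
        pred, _, _ = simulate_mat(mat, current, dt=dt)
        try:
            g = coincidence_factor(ref, pred, delta=config.gamma_delta).gamma
        except Exception:
            return 2.0
        return -g

    best_x, best_g, best_so_far = _optimize_gamma(neg_gamma, config)
    mat = _build_mat(best_x, config, tau_p)
    gamma_test = None
    if test is not None:
        cur_t, ref_t = test
        pred_t, _, _ = simulate_mat(mat, cur_t, dt=dt)
        gamma_test = coincidence_factor(ref_t, pred_t, delta=config.gamma_delta).gamma
    return ReductionResult(
        mat=mat,
        gamma_train=best_g,
        gamma_test=gamma_test,
        tau_p=tau_p,
        restart_gammas=np.array(best_so_far),
    )


def exponential_filter_closed_form(
    a: float, tau: float, tau_m: float, c_m: float, t: np.ndarray
) -> np.ndarray:
    """Closed form of (a e^{-s/tau}) * (e^{-s/tau_m}) / C_m at times t >= 0."""
    if abs(tau - tau_m) < 1e-9:
        return a * t * np.exp(-t / tau_m) / c_m
    pref = a * tau * tau_m / (tau - tau_m) / c_m
    return pref * (np.exp(-t / tau) - np.exp(-t / tau_m))


def assemble_theory_kernel(
    fits: Sequence,
    w_sp: float,
    delta_v: float,
    tau_m: float = 10.0,
    c_m: float = 1.0,
    t_max: float = 500.0,
    dt: float = 0.5,
) -> Tuple[ThresholdKernel, dict]:
    """Assemble the effective threshold kernel from first-principles pieces.

    ``fits`` is a sequence of :class:`KernelComponentFit` (eta and/or h
    components); ``w_sp`` (ms) and ``delta_v`` (mV, negative) are the spike
    width and the voltage change over the spike measured from the detailed
    waveform.  Returns the least-squares projection onto the MAT kernel
    family (time constants taken from the fits) together with a diagnostics
    dict holding the exact kernel samples and the projection residual.
    """
    if w_sp < 0:
        raise ValueError("w_sp must be >= 0")
    t = np.arange(dt, t_max + dt, dt)
    H = -delta_v * np.exp(-(t - w_sp) / tau_m)
    tau_p = None
    tau_ca = tau_s = None
    for f in fits:
        if f.ion == "M":
            tau_p = f.tau_slow[0]
            if f.kind == "eta":
                H = H + exponential_filter_closed_form(f.amplitude, tau_p, tau_m, c_m, t)
            else:
                H = H + f.amplitude * np.exp(-t / tau_p)
        elif f.ion == "AHP":
            tau_ca, tau_s = f.tau_slow
            if f.kind == "eta":
                H = H + exponential_filter_closed_form(
                    f.amplitude, tau_ca, tau_m, c_m, t
                ) - exponential_filter_closed_form(f.amplitude, tau_s, tau_m, c_m, t)
            else:
                H = H + f.amplitude * (np.exp(-t / tau_ca) - np.exp(-t / tau_s))
        else:
            raise ValueError(f"unknown ion {f.ion!r} in fits")
    # project onto the MAT family with the structural time constants
    cols = [np.exp(-t / tau_m)]
    if tau_p is not None:
        cols.append(np.exp(-t / tau_p))
    if tau_ca is not None:
        cols.append(np.exp(-t / tau_ca) - np.exp(-t / tau_s))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, H, rcond=None)
    resid = H - A @ coef
    k = 1
    alpha_m = alpha_ahp = 0.0
    if tau_p is not None:
        alpha_m = float(coef[k])
        k += 1
    if tau_ca is not None:
        alpha_ahp = float(coef[k])
    kernel = ThresholdKernel(
        alpha_0=float(coef[0]),
        tau_fast=tau_m,
        alpha_m=alpha_m,
        tau_p=tau_p if tau_p is not None else 150.0,
        alpha_ahp=alpha_ahp,
        tau_ca=tau_ca if tau_ca is not None else 200.0,
        tau_s=tau_s if tau_s is not None else 50.0,
    )
    info = {
        "t": t,
        "H_exact": H,
        "rms_residual": float(np.sqrt(np.mean(resid**2))),
    }
    return kernel, info


def extract_effective_kernel(
    params: ConductanceParams,
    ion: str,
    v_c: float = -70.0,
    h_lags: Optional[np.ndarray] = None,
    dt: float = 0.025,
) -> Tuple[ThresholdKernel, dict]:
    """Effective threshold kernel of a detailed neuron, built from probes.

    Runs the holding-plus-pulse protocol, extracts the spike-triggered slow
    current eta_ion and the threshold variation h_ion, measures the spike
    waveform statistics, and assembles the MAT kernel.  Deterministic (no
    noise enters the probes), so the resulting weights expose how the slow
    K+ parameters shape the kernel.
    """
    from .fixtures import no_adaptation_neuron
    from .threshold_probe import (
        HoldingProtocol,
        fit_eta,
        fit_h,
        spike_triggered_current,
        spike_waveform_stats,
        threshold_variation_h,
    )

    if h_lags is None:
        h_lags = np.array([20.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0])
    protocol = HoldingProtocol(params, v_c=v_c, dt=dt)
    eta_fit = fit_eta(spike_triggered_current(params, ion, v_c=v_c, dt=dt,
                                              protocol=protocol), params)
    reference = no_adaptation_neuron(
        **{f: getattr(params, f) for f in ConductanceParams.__dataclass_fields__
           if f not in ("g_m", "g_ahp")}
    )
    _, h = threshold_variation_h(params, reference, v_c, h_lags, dt=dt)
    h_fit = fit_h(h_lags, h, ion, params, v_bar=eta_fit.v_bar)
    w_sp, delta_v = spike_waveform_stats(protocol)
    kernel, info = assemble_theory_kernel([eta_fit, h_fit], w_sp=w_sp,
                                          delta_v=delta_v)
    info.update({"eta_fit": eta_fit, "h_fit": h_fit, "w_sp": w_sp,
                 "delta_v": delta_v})
    return kernel, info


@dataclass
class ProtocolRecord:
    """One OU input condition of the evaluation protocol."""

    mu: float
    sigma: float
    rate_train_hz: float
    rate_test_hz: float
    gamma_train: float
    gamma_test: float
    mat: MATParams
    tau_p: float


@dataclass
class ProtocolResult:
    records: list

    @property
    def mean_gamma_test(self) -> float:
        return float(np.mean([r.gamma_test for r in self.records]))

    @property
    def mean_gamma_train(self) -> float:
        return float(np.mean([r.gamma_train for r in self.records]))

    def mean_weight(self, name: str) -> float:
        return float(np.mean([getattr(r.mat.kernel, name) for r in self.records]))

    def table(self) -> list:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "mu": r.mu,
                    "sigma": r.sigma,
                    "rate_hz": r.rate_test_hz,
                    "gamma_train": r.gamma_train,
                    "gamma_test": r.gamma_test,
                }
            )
        return rows


def evaluate_protocol(
    params: ConductanceParams,
    inputs: Sequence[Tuple[float, float]],
    free: Tuple[str, ...],
    duration: float = 50000.0,
    dt: float = 0.025,
    seed: int = 0,
    tau_syn: float = 2.0,
    restarts: int = 5,
) -> ProtocolResult:
    """Run the full spike-prediction benchmark over a set of OU inputs.

    For each (mu, sigma) pair two independent OU currents of ``duration`` ms
    drive the detailed model; the reduced model is fitted on the first
    (training) set and scored by Gamma on the second (test) set.
    """
    from .hh_core import detect_spikes, simulate, steady_state
    from .stimuli import OUSpec, ou_current

    rest = steady_state(params, 0.0, dt=dt)
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(inputs)) % (2**31)
    records = []
    for i, (mu, sigma) in enumerate(inputs):
        cur_train = ou_current(
            OUSpec(mu=mu, sigma=sigma, tau_syn=tau_syn, seed=int(seeds[2 * i]), dt=dt),
            duration,
        )
        cur_test = ou_current(
            OUSpec(mu=mu, sigma=sigma, tau_syn=tau_syn, seed=int(seeds[2 * i + 1]), dt=dt),
            duration,
        )
        tr_train = simulate(params, cur_train, dt=dt, init=rest)
        tr_test = simulate(params, cur_test, dt=dt, init=rest)
        sp_train = detect_spikes(tr_train)
        sp_test = detect_spikes(tr_test)
        config = ReductionConfig(
            free=free, seed=int(seeds[2 * i]), restarts=restarts
        )
        fit = fit_mat(
            (cur_train, sp_train),
            config=config,
            dt=dt,
            v_trace=tr_train.v,
            test=(cur_test, sp_test),
        )
        records.append(
            ProtocolRecord(
                mu=mu,
                sigma=sigma,
                rate_train_hz=sp_train.rate_hz,
                rate_test_hz=sp_test.rate_hz,
                gamma_train=fit.gamma_train,
                gamma_test=fit.gamma_test,
                mat=fit.mat,
                tau_p=fit.tau_p,
            )
        )
    return ProtocolResult(records)
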