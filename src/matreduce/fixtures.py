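"""Named study conditions and seeded synthetic datasets.

All inputs of the study are generated internally; this module pins the
canonical conditions (the three neurons, the rectangular-current protocol,
the OU input grids of the spike-prediction benchmark) and provides seeded
generators for the datasets that tests and the command line consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .hh_core import ConductanceParams, SpikeTrain, Trace, detect_spikes, simulate, steady_state
from .mat_model import MATParams, ThresholdKernel, simulate_mat
from .stimuli import OUSpec, ou_current

# OU input grids of the spike-prediction benchmark: three moderately noisy
# (sigma = mu) then three highly noisy (sigma = 2 mu) conditions, targeting
# 5, 10 and 20 Hz in each series.
M_NEURON_INPUTS = [
    (1.98, 1.98),
    (2.45, 2.45),
    (3.24, 3.24),
    (1.33, 2.66),
    (1.65, 3.30),
    (2.22, 4.44),
]
AHP_NEURON_INPUTS = [
    (1.84, 1.84),
    (2.15, 2.15),
    (2.75, 2.75),
    (1.28, 2.56),
    (1.58, 3.16),
    (2.10, 4.20),
]


def no_adaptation_neuron(**overrides) -> ConductanceParams:
    return ConductanceParams(**{"g_m": 0.0, "g_ahp": 0.0, **overrides})


def m_neuron(g_m: float = 0.2, **overrides) -> ConductanceParams:
    """Neuron whose adaptation is carried by the M-type K+ current."""
    return ConductanceParams(**{"g_m": g_m, "g_ahp": 0.0, **overrides})


def ahp_neuron(g_ahp: float = 0.2, **overrides) -> ConductanceParams:
    """Neuron whose adaptation is carried by the Ca2+-activated K+ current."""
    return ConductanceParams(**{"g_m": 0.0, "g_ahp": g_ahp, **overrides})


def rectangular_current(
    amplitude: float,
    duration: float = 1500.0,
    onset: float = 200.0,
    offset: float = 1300.0,
    dt: float = 0.025,
) -> np.ndarray:
    n = int(round(duration / dt))
    stim = np.zeros(n)
    stim[int(round(onset / dt)) : int(round(offset / dt))] = amplitude
    return stim


def adaptation_demo_traces(dt: float = 0.025) -> dict:
    """Rectangular-current responses of the three canonical neurons.

    Amplitudes are matched to the neurons' rheobase regimes: 2.5 uA/cm^2 for
    the non-adapting neuron, 3.2 for the M-current neuron (g_M = 0.1), 3.1
    for the AHP neuron (g_AHP = 0.2).
    """
    conditions = {
        "no_adaptation": (no_adaptation_neuron(), 2.5),
        "I_M": (m_neuron(g_m=0.1), 3.2),
        "I_AHP": (ahp_neuron(), 3.1),
    }
    out = {}
    for name, (params, amp) in conditions.items():
        stim = rectangular_current(amp, dt=dt)
        out[name] = simulate(params, stim, dt=dt)
    return out


@dataclass
class IOCondition:
    """One input-output pair for reduction: current, voltage, spikes."""

    mu: float
    sigma: float
    current: np.ndarray
    trace: Trace
    spikes: SpikeTrain


def detailed_io_dataset(
    params: ConductanceParams,
    mu: float,
    sigma: float,
    duration: float = 50000.0,
    seed: int = 0,
    dt: float = 0.025,
    tau_syn: float = 2.0,
) -> IOCondition:
    """Detailed-model response to one OU current, starting from rest."""
    rest = steady_state(params, 0.0, dt=dt)
    cur = ou_current(OUSpec(mu=mu, sigma=sigma, tau_syn=tau_syn, seed=seed, dt=dt), duration)
    tr = simulate(params, cur, dt=dt, init=rest)
    return IOCondition(mu, sigma, cur, tr, detect_spikes(tr))


RECOVERY_TRUE_PARAMS = dict(theta_inf=30.0, alpha_0=35.0, alpha_m=4.0, tau_p=150.0)


def mat_recovery_dataset(
    seed: int = 0,
    duration: float = 50000.0,
    dt: float = 0.025,
    mu: float = 3.6,
    sigma: float = 1.2,
):
    """OU-driven spikes from a MAT model with known (planted) parameters.

    Returns (true MATParams, current series, spike train); used for
    parameter-recovery checks of the Gamma-maximization fit.
    """
    kernel = ThresholdKernel(
        alpha_0=RECOVERY_TRUE_PARAMS["alpha_0"],
        tau_fast=10.0,
        alpha_m=RECOVERY_TRUE_PARAMS["alpha_m"],
        tau_p=RECOVERY_TRUE_PARAMS["tau_p"],
    )
    true = MATParams(theta_inf=RECOVERY_TRUE_PARAMS["theta_inf"], kernel=kernel)
    cur = ou_current(OUSpec(mu=mu, sigma=sigma, seed=seed, dt=dt), duration)
    spikes, _, _ = simulate_mat(true, cur, dt=dt)
    return true, cur, spikes


def generate_fixtures(seed: int, outdir: Optional[str] = None) -> dict:
    """Produce the named fixture bundle (seeded, reproducible).

    Bundle contents: the rectangular-current demonstration traces, one
    moderate-noise input-output condition per neuron type (shortened to 20 s
    to keep the bundle light), and the MAT recovery dataset.  When
    ``outdir`` is given the artifacts are also written as text files.
    """
    from . import io as mio

    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    bundle = {
        "demo": adaptation_demo_traces(),
        "m_condition": detailed_io_dataset(
            m_neuron(), *M_NEURON_INPUTS[1], duration=20000.0, seed=int(ss[0])
        ),
        "ahp_condition": detailed_io_dataset(
            ahp_neuron(), *AHP_NEURON_INPUTS[1], duration=20000.0, seed=int(ss[1])
        ),
        "mat_recovery": mat_recovery_dataset(seed=int(ss[2]), duration=20000.0),
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": seed}
        for name, tr in bundle["demo"].items():
            mio.write_trace(out / f"demo_{name}.csv", tr, meta=meta)
        for key in ("m_condition", "ahp_condition"):
            cond = bundle[key]
            mio.write_trace(out / f"{key}.csv", cond.trace, meta=meta)
            mio.write_spikes(out / f"{key}.spk", cond.spikes, meta=meta)
        true, cur, spikes = bundle["mat_recovery"]
        mio.write_spikes(out / "mat_recovery.spk", spikes, meta=meta)
        mio.save_json(out / "mat_recovery_true.json", mio.mat_params_to_dict(true))
    return bundle
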