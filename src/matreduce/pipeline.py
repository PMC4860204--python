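"""Config-driven orchestration: simulate -> fit -> evaluate.

A single flat mapping drives a run; every artifact carries a provenance
sidecar (config hash + seed) sufficient to regenerate it.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from . import io as mio
from .exceptions import ConfigError
from .hh_core import detect_spikes, simulate, steady_state
from .reduction import ReductionConfig, fit_mat
from .evaluation import coincidence_factor
from .stimuli import OUSpec, ou_current, pulse_current, PulseSpec

log = logging.getLogger("matreduce")


def _require(config: dict, *keys):
    missing = [k for k in keys if k not in config]
    if missing:
        raise ConfigError(f"missing config keys: {missing}")


def _build_stimulus(config: dict, dt: float) -> np.ndarray:
    _require(config, "stimulus", "duration")
    spec = config["stimulus"]
    kind = spec.get("kind")
    n = int(round(config["duration"] / dt))
    if kind == "ou":
        return ou_current(
            OUSpec(
                mu=float(spec["mu"]),
                sigma=float(spec["sigma"]),
                tau_syn=float(spec.get("tau_syn", 2.0)),
                seed=int(config.get("seed", 0)),
                dt=dt,
            ),
            config["duration"],
        )
    if kind == "pulse":
        grid = np.arange(n) * dt
        return pulse_current(
            PulseSpec(
                i_c=float(spec.get("i_c", 0.0)),
                q_c=float(spec.get("q_c", 0.0)),
                t_p=float(spec.get("t_p", 0.0)),
            ),
            grid,
        )
    if kind == "constant":
        return np.full(n, float(spec.get("amplitude", 0.0)))
    raise ConfigError(f"unknown stimulus kind {kind!r}")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the stages listed in ``config['stages']``.

    Supported stages: ``simulate`` (detailed model under the configured
    stimulus), ``fit`` (Gamma-maximization reduction on the simulated data),
    ``evaluate`` (coincidence factor of the fit against the simulated
    spikes).  Validation happens before any compute; a stage failure aborts
    with the stage name.
    """
    _require(config, "stages")
    stages = list(config["stages"])
    known = {"simulate", "fit", "evaluate"}
    unknown = set(stages) - known
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    dt = float(config.get("dt", 0.025))
    if dt <= 0 or float(config.get("duration", 1.0)) <= 0:
        raise ConfigError("dt and duration must be positive")
    if "simulate" in stages:
        _require(config, "neuron", "stimulus", "duration")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "version": __version__,
        "seed": int(config.get("seed", 0)),
        "config_hash": mio.config_hash(config),
    }
    artifacts: dict = {"provenance": provenance}
    timings = {}
    trace = spikes = current = None
    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                params = mio.conductance_params_from_dict(config["neuron"])
                current = _build_stimulus(config, dt)
                init = steady_state(params, 0.0, dt=dt)
                trace = simulate(params, current, dt=dt, init=init)
                spikes = detect_spikes(trace)
                mio.write_trace(outdir / "trace.csv", trace, meta=provenance)
                mio.write_spikes(outdir / "spikes.spk", spikes, meta=provenance)
                artifacts["n_spikes"] = spikes.n
                artifacts["rate_hz"] = spikes.rate_hz
            elif stage == "fit":
                if trace is None:
                    raise ConfigError("fit stage requires a prior simulate stage")
                rc = ReductionConfig(
                    free=tuple(config.get("free", ("theta_inf", "alpha_0", "alpha_m"))),
                    seed=int(config.get("seed", 0)),
                )
                fit = fit_mat((current, spikes), config=rc, dt=dt, v_trace=trace.v)
                mio.save_json(
                    outdir / "mat.json",
                    {**mio.mat_params_to_dict(fit.mat), "gamma_train": fit.gamma_train},
                )
                artifacts["fit"] = fit
            elif stage == "evaluate":
                if "fit" not in artifacts:
                    raise ConfigError("evaluate stage requires a prior fit stage")
                from .mat_model import simulate_mat

                pred, _, _ = simulate_mat(artifacts["fit"].mat, current, dt=dt)
                g = coincidence_factor(spikes, pred)
                mio.save_json(
                    outdir / "gamma.json",
                    {"gamma": g.gamma, "n_c": g.n_c, "n_d": g.n_d, "n_m": g.n_m},
                )
                artifacts["gamma"] = g.gamma
        except ConfigError:
            raise
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        timings[stage] = time.time() - t0
        log.info("stage %s finished in %.2f s", stage, timings[stage])
    artifacts["timings"] = timings
    mio.save_json(outdir / "run_log.json", {"provenance": provenance, "timings": timings})
    return artifacts
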