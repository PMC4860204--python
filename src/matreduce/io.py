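"""Text serialization of traces, spike trains, parameters, and configs.

Traces travel as columnar CSV (header ``t,V,I_ex[,I_L,I_Na,I_Kd,I_M,I_Ca,
I_AHP]``) with a JSON sidecar recording dt, units, and provenance; spike
trains as one time (ms) per line with a ``# duration_ms=`` header line.
Values are written with full precision so a write-read round trip is exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParseError
from .hh_core import CURRENT_NAMES, ConductanceParams, SpikeTrain, Trace
from .mat_model import MATParams, ThresholdKernel

UNITS = {
    "t": "ms",
    "V": "mV",
    "I_ex": "uA/cm^2",
    **{name: "uA/cm^2" for name in CURRENT_NAMES},
}

# Flat config keys follow the field-standard symbols (g_M, tau_max, ...)
_COND_KEYS = {
    "C_m": "c_m",
    "g_L": "g_l",
    "g_Na": "g_na",
    "g_Kd": "g_kd",
    "g_M": "g_m",
    "g_Ca": "g_ca",
    "g_AHP": "g_ahp",
    "E_L": "e_l",
    "E_Na": "e_na",
    "E_K": "e_k",
    "E_Ca": "e_ca",
    "tau_max": "tau_max",
    "beta_s": "beta_s",
    "tau_Ca": "tau_ca",
    "Ca_inf": "ca_inf",
    "F": "faraday",
}


def conductance_params_to_dict(p: ConductanceParams) -> dict:
    return {k: getattr(p, attr) for k, attr in _COND_KEYS.items()}


def conductance_params_from_dict(d: dict) -> ConductanceParams:
    kwargs = {}
    for k, v in d.items():
        if k not in _COND_KEYS:
            raise KeyError(f"unknown conductance parameter {k!r}")
        kwargs[_COND_KEYS[k]] = float(v)
    return ConductanceParams(**kwargs)


def mat_params_to_dict(p: MATParams) -> dict:
    k = p.kernel
    return {
        "theta_inf": p.theta_inf,
        "alpha_0": k.alpha_0,
        "alpha_M": k.alpha_m,
        "tau_p": k.tau_p,
        "alpha_AHP": k.alpha_ahp,
        "tau_Ca": k.tau_ca,
        "tau_s": k.tau_s,
        "tau_m": p.tau_m,
        "C_m": p.c_m,
        "refractory": p.refractory,
    }


def mat_params_from_dict(d: dict) -> MATParams:
    kernel = ThresholdKernel(
        alpha_0=float(d["alpha_0"]),
        tau_fast=float(d.get("tau_m", 10.0)),
        alpha_m=float(d.get("alpha_M", 0.0)),
        tau_p=float(d.get("tau_p", 150.0)),
        alpha_ahp=float(d.get("alpha_AHP", 0.0)),
        tau_ca=float(d.get("tau_Ca", 200.0)),
        tau_s=float(d.get("tau_s", 50.0)),
    )
    return MATParams(
        theta_inf=float(d["theta_inf"]),
        kernel=kernel,
        tau_m=float(d.get("tau_m", 10.0)),
        c_m=float(d.get("C_m", 1.0)),
        refractory=float(d.get("refractory", 2.0)),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable object, for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_trace(path: Union[str, Path], trace: Trace, meta: Optional[dict] = None):
    path = Path(path)
    cols = {"t": trace.t, "V": trace.v, "I_ex": trace.i_ex}
    if trace.currents is not None:
        for j, name in enumerate(CURRENT_NAMES):
            cols[name] = trace.currents[:, j]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "dt": trace.dt,
        "columns": list(cols),
        "units": {c: UNITS[c] for c in cols},
        "meta": meta or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_trace(path: Union[str, Path]) -> Trace:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # surface the offending line when pandas knows it
        line = getattr(e, "lineno", 0) or 0
        raise ParseError(path, line, str(e)) from e
    for col in ("t", "V", "I_ex"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing required column {col!r}")
    t = df["t"].to_numpy()
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ParseError(path, 1, "time grid is not uniform")
        dt = float(steps[0])
    else:
        dt = 0.025
    currents = None
    if all(name in df.columns for name in CURRENT_NAMES):
        currents = df[list(CURRENT_NAMES)].to_numpy()
    return Trace(
        t=t,
        v=df["V"].to_numpy(),
        i_ex=df["I_ex"].to_numpy(),
        dt=dt,
        currents=currents,
    )


def write_spikes(path: Union[str, Path], train: SpikeTrain, meta: Optional[dict] = None):
    path = Path(path)
    lines = [f"# duration_ms={train.duration:.17g}"]
    if meta:
        lines.append("# meta=" + json.dumps(meta, sort_keys=True, default=float))
    lines += [f"{t:.17g}" for t in train.times]
    path.write_text("\n".join(lines) + "\n")


def read_spikes(path: Union[str, Path]) -> SpikeTrain:
    path = Path(path)
    duration = None
    times = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "duration_ms=" in line:
                try:
                    duration = float(line.split("duration_ms=")[1].split()[0])
                except ValueError as e:
                    raise ParseError(path, lineno, "bad duration header") from e
            continue
        try:
            t = float(line)
        except ValueError as e:
            raise ParseError(path, lineno, f"not a number: {line!r}") from e
        if times and t <= times[-1]:
            raise ParseError(path, lineno, "spike times not strictly increasing")
        times.append(t)
    if duration is None:
        duration = times[-1] if times else 0.0
    return SpikeTrain(np.array(times), duration)


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(path, 1, "config must be a mapping")
    return cfg


def save_json(path: Union[str, Path], obj):
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))
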