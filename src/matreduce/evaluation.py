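"""Spike-train comparison and interspike-interval statistics.

The coincidence factor

    Gamma = (N_c - <N_c>) / (N_d + N_m) * 2 / (1 - 2 nu Delta)

counts one-to-one coincidences N_c within a window Delta between a reference
(detailed-model) train of N_d spikes and a prediction of N_m spikes,
corrected for the chance coincidences <N_c> = 2 nu N_d Delta of a Poisson
process firing at the prediction's rate nu.  Gamma = 1 only when every
spike coincides; a rate-matched Poisson prediction scores 0 on average.
Note the definition is asymmetric: nu always comes from the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateRateError
from .hh_core import SpikeTrain


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n_c: int  # matched coincidences
    n_d: int  # reference (detailed-model) spike count
    n_m: int  # prediction (reduced-model) spike count
    expected_nc: float  # 2 nu N_d Delta
    nu: float  # prediction rate, spikes/ms
    delta: float  # coincidence window, ms


def greedy_coincidences(ref: np.ndarray, pred: np.ndarray, delta: float) -> int:
    """One-to-one in-order matching count with tolerance |t_r - t_p| <= delta.

    Two pointers advance through the sorted trains; a pair within delta is
    matched (each spike at most once), otherwise the earlier train advances.
    For this interval structure the greedy count equals the maximum bipartite
    matching.
    """
    i = j = n_c = 0
    while i < ref.size and j < pred.size:
        d = ref[i] - pred[j]
        if abs(d) <= delta:
            n_c += 1
            i += 1
            j += 1
        elif d > 0:
            j += 1
        else:
            i += 1
    return n_c


def coincidence_factor(
    reference: SpikeTrain,
    prediction: SpikeTrain,
    delta: float = 4.0,
) -> GammaResult:
    """Coincidence factor of a predicted spike train against a reference."""
    duration = reference.duration
    if duration <= 0:
        raise ValueError("reference duration must be > 0")
    n_d, n_m = reference.n, prediction.n
    nu = n_m / prediction.duration if prediction.duration > 0 else 0.0
    norm = 1.0 - 2.0 * nu * delta
    if norm <= 0:
        raise DegenerateRateError(
            f"1 - 2*nu*Delta = {norm:.4f} <= 0 (nu = {nu:.4f}/ms, Delta = {delta} ms)"
        )
    n_c = greedy_coincidences(reference.times, prediction.times, delta)
    expected = 2.0 * nu * n_d * delta
    if n_d + n_m == 0:
        gamma = 0.0  # two empty trains carry no information
    elif n_c == n_d == n_m:
        gamma = 1.0  # full coincidence: algebraically exact
    else:
        gamma = (n_c - expected) / (n_d + n_m) * 2.0 / norm
    return GammaResult(gamma, n_c, n_d, n_m, expected, nu, delta)


@dataclass(frozen=True)
class ISIStats:
    """Firing rate and interspike-interval statistics.

    Undefined quantities (too few spikes, zero ISI variance) are ``None``
    rather than fabricated.
    """

    rate_hz: float
    cv: Optional[float]
    rho1: Optional[float]
    n_isi: int


def isi_stats(train: SpikeTrain) -> ISIStats:
    """Rate, coefficient of variation, and lag-1 serial ISI correlation.

    cv = SD(ISI)/mean(ISI) needs at least 2 intervals; rho1 is the lag-1
    Pearson correlation of consecutive ISIs and needs at least 3 intervals
    and non-zero variance.
    """
    rate = train.rate_hz
    isis = train.isis
    n_isi = isis.size
    cv = rho1 = None
    if n_isi >= 2:
        m = isis.mean()
        sd = isis.std(ddof=0)
        cv = float(sd / m)
    if n_isi >= 3 and np.ptp(isis) > 0:
        x, y = isis[:-1], isis[1:]
        if x.std() > 0 and y.std() > 0:
            rho1 = float(np.corrcoef(x, y)[0, 1])
    return ISIStats(rate, cv, rho1, n_isi)
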