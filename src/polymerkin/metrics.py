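"""Filament-formation metrics and closed-form steady states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .integrate import DistributionTimeCourse
from .rates import RateSet

__all__ = [
    "FilamentMetrics",
    "filament_metrics",
    "equilibrium_single_state",
]

SUBUNIT_MASS_KDA = 42.0


@dataclass(frozen=True)
class FilamentMetrics:
    frac_mass_above_140kDa: float
    frac_mass_above_150mers: float
    mean_length: float  # number-averaged, subunits


def filament_metrics(
    dist: DistributionTimeCourse,
    subunit_mass_kDa: float = SUBUNIT_MASS_KDA,
) -> pd.DataFrame:
    """Per-time filament metrics.

    ``frac_mass_above_140kDa`` is the fraction of total subunit mass held in
    species whose mass i*subunit_mass strictly exceeds 140 kDa (i >= 4 for
    42-kDa subunits); ``frac_mass_above_150mers`` analogously for species of
    strictly more than 150 subunits.
    """
    sizes = dist.sizes.astype(float)
    conc = dist.total_per_size()
    mass_per_size = conc * sizes  # subunit concentration per species
    total = mass_per_size.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total subunit mass; metrics undefined")
    above_140 = sizes * subunit_mass_kDa > 140.0
    above_150 = sizes > 150
    number = conc.sum(axis=1)
    return pd.DataFrame(
        {
            "time_s": dist.times,
            "frac_mass_above_140kDa": mass_per_size[:, above_140].sum(axis=1) / total,
            "frac_mass_above_150mers": mass_per_size[:, above_150].sum(axis=1) / total,
            "mean_length": total / number,
        }
    )


def _mass_given_monomer(x: float, ratios: np.ndarray) -> float:
    """Total subunit mass of the detailed-balance distribution with free
    monomer ``x``: [A_{i+1}] = ratios[i] * x * [A_i].  Log-space to survive
    super-critical ratios at large n."""
    n = ratios.size + 1
    logc = np.empty(n)
    logc[0] = np.log(x)
    logr = np.log(ratios * x)
    logc[1:] = logc[0] + np.cumsum(logr)
    logm = logc + np.log(np.arange(1, n + 1))
    peak = logm.max()
    if peak > 690.0:  # mass astronomically large; report a huge finite value
        return 1e300
    return float(np.exp(peak) * np.exp(logm - peak).sum())


def equilibrium_single_state(
    rates: RateSet,
    total_conc: float,
    n_max: int,
) -> np.ndarray:
    """Detailed-balance steady state of the single-state scheme.

    Solves [A_{i+1}] = (k_i / k_-i) [A][A_i] with the free monomer chosen by
    a monotone scalar root-find so that total subunit mass equals
    ``total_conc``.  The result is a fixed point of the scheme's RHS.
    """
    if total_conc <= 0:
        raise ValueError("total_conc must be positive")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    ka = np.full(n_max - 1, rates.k4)
    kd = np.full(n_max - 1, rates.km4)
    ka[0], kd[0] = rates.k1, rates.km1
    if n_max >= 3:
        ka[1], kd[1] = rates.k2, rates.km2
    if n_max >= 4:
        ka[2], kd[2] = rates.k3, rates.km3
    if np.any(kd <= 0):
        raise ValueError("all dissociation rates must be > 0")
    ratios = ka / kd

    f = lambda x: _mass_given_monomer(x, ratios) - total_conc
    lo = total_conc * 1e-14
    if f(lo) > 0 or f(total_conc) < 0:
        raise ValueError("no equilibrium root in (0, total_conc]")
    x = brentq(f, lo, total_conc, xtol=1e-300, rtol=1e-14)
    conc = np.empty(n_max)
    conc[0] = x
    for i in range(1, n_max):
        conc[i] = conc[i - 1] * ratios[i - 1] * x
    return conc
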