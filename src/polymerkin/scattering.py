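"""Bulk light-scattering forward model.

The scattering contribution of an oligomer scales with its concentration
and the square of its molecular mass (number of subunits), so the signal
of a polymerizing solution is s · Σ_{i=sds}^{n} i² [A_i], where ``sds`` is
the smallest species the photodetector can see (a detection floor, in
subunits) and ``s`` an arbitrary-units scale factor.  Simulated traces are
mapped onto experimental ones by matching the average start and end levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .integrate import DistributionTimeCourse

__all__ = [
    "ScatteringParams",
    "ScatteringTrace",
    "scattering_signal",
    "scale_to_experiment",
]


@dataclass(frozen=True)
class ScatteringParams:
    """Detection floor ``sds`` (subunits), scale ``s`` (a.u. per µM·subunit²)
    and the largest simulated species ``n``."""

    sds: int = 30
    s: float = 1.0
    n: int = 2000

    def __post_init__(self):
        if not (1 <= self.sds <= self.n):
            raise ValueError("require 1 <= sds <= n")
        if self.s <= 0:
            raise ValueError("scale s must be > 0")


@dataclass(frozen=True)
class ScatteringTrace:
    """(time, signal) series in arbitrary units on a uniform time grid."""

    times: np.ndarray
    signal: np.ndarray
    params: ScatteringParams | None = None
    provenance: str = "simulated"  # simulated | experimental | synthetic

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.size != y.size or t.size < 1:
            raise ValueError("times and signal must be equal-length 1-D arrays")
        if t.size > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if self.provenance not in ("simulated", "experimental", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame({"time_s": self.times, "signal_au": self.signal}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {"provenance": self.provenance}
            if self.params is not None:
                meta.update(sds=self.params.sds, s=self.params.s, n=self.params.n)
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path, provenance: str = "experimental") -> "ScatteringTrace":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            signal=df["signal_au"].to_numpy(),
            provenance=provenance,
        )


def scattering_signal(
    dist: DistributionTimeCourse, params: ScatteringParams
) -> ScatteringTrace:
    """Forward-model the scattering trace from a concentration time course.

    signal(t) = s · Σ_{i=sds}^{n} i² ([A_i](t) + [A'_i](t)); primed and
    unprimed species of the same size scatter identically.
    """
    n_avail = dist.model.n_max
    n = min(params.n, n_avail)
    if params.sds > n:
        raise ValueError(f"sds={params.sds} exceeds largest species {n}")
    conc = dist.total_per_size()[:, params.sds - 1: n]
    sizes = np.arange(params.sds, n + 1, dtype=float)
    sig = params.s * conc @ (sizes**2)
    return ScatteringTrace(
        times=dist.times, signal=sig, params=params, provenance="simulated"
    )


def scale_to_experiment(
    sim: ScatteringTrace,
    exp: ScatteringTrace,
    window: int = 10,
    affine: bool = True,
) -> ScatteringTrace:
    """Scale a simulated trace onto an experimental one.

    Solves for the map a·signal + b such that the simulated means over the
    first and last ``window`` points equal the corresponding experimental
    means (exact two-point affine solve).  With ``affine=False`` only the
    scale a is fitted (b = 0) by least squares on the two window means.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(sim) or window > len(exp):
        raise ValueError("window exceeds trace length")
    s0, s1 = float(np.mean(sim.signal[:window])), float(np.mean(sim.signal[-window:]))
    e0, e1 = float(np.mean(exp.signal[:window])), float(np.mean(exp.signal[-window:]))
    if affine:
        if np.isclose(s0, s1):
            if np.isclose(e0, e1):
                a, b = 1.0, e0 - s0
            else:
                raise ValueError(
                    "flat simulated trace cannot be mapped onto distinct "
                    "experimental start/end levels"
                )
        else:
            a = (e1 - e0) / (s1 - s0)
            b = e0 - a * s0
    else:
        denom = s0 * s0 + s1 * s1
        if denom == 0:
            raise ValueError("all-zero simulated trace cannot be scaled")
        a, b = (s0 * e0 + s1 * e1) / denom, 0.0
    return replace(sim, signal=a * sim.signal + b)
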