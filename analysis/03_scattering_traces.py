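#!/usr/bin/env python
"""Bulk light-scattering time courses of the two transition models.

Simulates 2 µM polymerizing actin under the ATP-hydrolysis and the
cation-exchange parameterizations and forward-models the scattering signal
s · Σ i²[A_i] above the detection floor.  Both traces rise sigmoid-like
from baseline to plateau; the cation model (AMP-PNP conditions) reaches a
higher amplitude, mirroring the stronger scattering increase observed for
non-hydrolysable nucleotide.

Writes results/03_scattering_<model>.csv.
"""

from pathlib import Path

import numpy as np

import polymerkin as pk
from polymerkin.integrate import SolverConfig
from polymerkin.scattering import ScatteringParams

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
QUIET = SolverConfig(truncation_warn=False)

#: Desk-scale truncation; raise towards 2000 to refine the plateau level.
N_MAX = 600


def main() -> None:
    grid = np.arange(0, 1800) * 2.0  # 1800 points at the 2-s read interval
    params = ScatteringParams(sds=30, s=100.0, n=N_MAX)
    for name, rates in (
        ("atp_hydrolysis", pk.atp_hydrolysis_rates()),
        ("cation_exchange", pk.cation_exchange_rates()),
    ):
        model = pk.build_two_state_model(rates, N_MAX, total_conc=2.0)
        dist = pk.integrate_model(model, grid, QUIET)
        trace = pk.scattering_signal(dist, params)
        trace.to_csv(OUT / f"03_scattering_{name}.csv")
        sig = trace.signal
        half = grid[np.argmax(sig >= sig[-1] / 2)]
        print(
            f"{name}: plateau {sig[-1]:.3g} a.u., half-rise at {half:.0f} s, "
            f"monotone after onset: {bool(np.all(np.diff(sig[60:]) > -1e-9))}"
        )


if __name__ == "__main__":
    main()
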