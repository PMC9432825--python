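#!/usr/bin/env python
"""Forward-model mass-photometry acquisitions and close the analysis loop.

Generates synthetic landing-event lists from the ATP-hydrolysis model at
900 nM (Gaussian mass peaks, diffusion-biased landing rates, 87.6% monomer
detection efficiency), then runs the full reverse analysis — display
histogram, Gaussian mixture fit of the resolved peaks, 42-kDa binning,
landing-rate upscale, count-to-concentration conversion — and reports how
well the generating subunit-mass fractions are recovered.

Writes results/02_mp_events_t<min>.csv and 02_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import polymerkin as pk
from polymerkin.integrate import SolverConfig
from polymerkin.mp import histogram_events
from polymerkin.synthetic import fixture_presets, generate_mp_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
QUIET = SolverConfig(truncation_warn=False)


def main() -> None:
    preset = fixture_presets()["atp_hydrolysis_900nM"].scaled(
        n_max=200, mp_target_events=20000
    )
    ds = generate_mp_dataset(preset, seed=42, solver=QUIET)
    rows = []
    for ev in ds.events:
        ev.to_csv(OUT / f"02_mp_events_t{ev.time_label_min:g}min.csv")
        frac_big = float(np.mean(ev.masses > 140.0))
        rows.append({"time_min": ev.time_label_min, "frac_events_above_140kDa": frac_big})
        print(
            f"t = {ev.time_label_min:4.0f} min: {len(ev)} events, "
            f"{frac_big:.3%} above 140 kDa (filaments are long but few, and "
            "land more slowly than monomers)"
        )
    pd.DataFrame(rows).to_csv(OUT / "02_event_fractions.csv", index=False)

    # close the loop at the last time point
    ev = ds.events[-1]
    centers, counts = histogram_events(ev, bin_width=4.0)
    low = centers < 3 * 42.0 + 21.0
    comps = pk.fit_gaussian_mixture(centers[low], counts[low], 3)
    species = pk.counts_from_events(ev, comps)
    conc = pk.counts_to_concentrations(
        pk.landing_rate_correction(species, "upscale"), total_conc=0.9
    )
    truth_A, truth_Ap = ds.truth.at_time(ev.time_label_min * 60.0)
    n = min(conc.size, truth_A.size)
    sizes = np.arange(1, n + 1)
    df = pd.DataFrame(
        {
            "species": sizes,
            "recovered_subunit_fraction": conc[:n] * sizes / 0.9,
            "true_subunit_fraction": (truth_A + truth_Ap)[:n] * sizes / 0.9,
        }
    )
    df.to_csv(OUT / "02_recovery.csv", index=False)
    err = np.abs(df.recovered_subunit_fraction - df.true_subunit_fraction)
    print(
        f"monomer fraction recovered to {err.iloc[0]:.4f} absolute "
        f"(true {df.true_subunit_fraction.iloc[0]:.3f})"
    )


if __name__ == "__main__":
    main()
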