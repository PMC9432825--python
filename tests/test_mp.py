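"""Mass-photometry bookkeeping: peak fitting, binning, corrections."""

from math import log, pi

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polymerkin.mp import (
    DiffusionParams,
    GaussianComponent,
    MassEventList,
    MixtureFitError,
    SpeciesCounts,
    concentrations_to_counts,
    counts_from_events,
    counts_to_concentrations,
    diffusion_coefficient,
    fit_gaussian_mixture,
    histogram_events,
    landing_rate_correction,
    species_index_of_mass,
    synthesize_mass_events,
)

BOLTZMANN = 1.380649e-23


# -- diffusion coefficients -------------------------------------------------


def test_monomer_diffusion_coefficient_is_reference_value():
    assert diffusion_coefficient(1) == pytest.approx(7.9e-7)


def test_sphere_scaling_cube_root():
    assert diffusion_coefficient(2) == pytest.approx(7.9e-7 * 2 ** (-1 / 3))
    assert diffusion_coefficient(4) == pytest.approx(7.9e-7 * 4 ** (-1 / 3))


def test_rod_formula_pentamer_hand_value():
    """Independent evaluation of the rod formula for i=5 (L=13.5 nm, d=7 nm,
    T=293.15 K, η=1e-3 Pa s)."""
    L = 5 * 2.7e-9
    p = 13.5 / 7.0
    v = 0.312 + 0.565 / p - 0.1 / p**2
    d_hand = BOLTZMANN * 293.15 * (log(p) + v) / (3 * pi * 1e-3 * L) * 1e4
    assert diffusion_coefficient(5) == pytest.approx(d_hand, rel=1e-12)
    assert d_hand == pytest.approx(3.9e-7, rel=0.02)


def test_diffusion_monotone_within_each_regime():
    i = np.arange(1, 40)
    d = diffusion_coefficient(i)
    assert np.all(np.diff(d[:4]) < 0)  # spheres 1..4
    assert np.all(np.diff(d[4:]) < 0)  # rods 5..
    with pytest.raises(ValueError):
        diffusion_coefficient(0)
    with pytest.raises(ValueError):
        DiffusionParams(viscosity_pa_s=-1.0)


# -- mixture fitting --------------------------------------------------------


def _gaussian_hist(params, bw=4.0, lo=20.0, hi=160.0):
    centers = np.arange(lo, hi, bw)
    y = np.zeros_like(centers)
    for area, mu, sd in params:
        y += area * bw / (sd * np.sqrt(2 * pi)) * np.exp(
            -0.5 * ((centers - mu) / sd) ** 2
        )
    return centers, y


def test_single_gaussian_recovered_within_2pct():
    centers, y = _gaussian_hist([(1000.0, 42.0, 8.0)])
    (c,) = fit_gaussian_mixture(centers, y, 1)
    assert c.area == pytest.approx(1000.0, rel=0.02)
    assert c.mean == pytest.approx(42.0, rel=0.02)
    assert c.sd == pytest.approx(8.0, rel=0.02)


def test_two_component_area_ratio_within_5pct():
    centers, y = _gaussian_hist([(1000.0, 42.0, 8.0), (250.0, 84.0, 9.0)])
    c1, c2 = fit_gaussian_mixture(centers, y, 2)
    assert c1.area / c2.area == pytest.approx(4.0, rel=0.05)


def test_empty_histogram_is_an_error():
    centers = np.arange(20.0, 160.0, 4.0)
    with pytest.raises(MixtureFitError):
        fit_gaussian_mixture(centers, np.zeros_like(centers), 2)


# -- event binning ----------------------------------------------------------


def test_bin_edges_half_open():
    assert species_index_of_mass([125.9]) == [3]
    assert species_index_of_mass([105.0]) == [3]  # midpoint goes up
    assert species_index_of_mass([104.999]) == [2]
    assert species_index_of_mass([21.0]) == [1]


def test_counts_from_events_exact_masses():
    ev = MassEventList(masses=np.array([42.0, 84.0, 84.0]))
    comps = [GaussianComponent(mean=42.0, sd=1.0, area=1.0, species_index=1)]
    counts = counts_from_events(ev, comps)
    assert counts.counts[0] == 1.0  # from the component area
    assert counts.counts[1] == 2.0  # binned


def test_counts_from_events_requires_contiguous_components():
    ev = MassEventList(masses=np.array([42.0]))
    comps = [GaussianComponent(mean=84.0, sd=1.0, area=1.0, species_index=2)]
    with pytest.raises(ValueError, match="1..m"):
        counts_from_events(ev, comps)


# -- count <-> concentration ------------------------------------------------


def test_counts_to_concentrations_hand_case():
    counts = SpeciesCounts(counts=np.array([50.0, 25.0]))
    conc = counts_to_concentrations(counts, total_conc=1.0)
    assert conc[0] == pytest.approx(0.5)
    assert conc[1] == pytest.approx(0.25)


def test_counts_to_concentrations_single_species_and_zero():
    conc = counts_to_concentrations(SpeciesCounts(np.array([100.0])), 1.0)
    assert conc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        counts_to_concentrations(SpeciesCounts(np.array([0.0, 0.0])), 1.0)


def test_concentrations_to_counts_hand_case():
    # equal subunit mass in monomers and trimers
    conc = np.array([0.3, 0.0, 0.1])
    counts = concentrations_to_counts(conc, n_total=600)
    assert counts.counts[0] == 300.0
    assert counts.counts[2] == 100.0


def test_concentrations_to_counts_sums_primed():
    counts = concentrations_to_counts(
        np.array([0.3, 0.0, 0.05]), n_total=600, conc_Aprime=np.array([0, 0, 0.05])
    )
    assert counts.counts[2] == 100.0


def test_round_half_even_rule():
    # N_subunits/i = 2.5 for species 2 -> rounds to 2 (banker's rounding)
    conc = np.array([1.0, 2.5])
    counts = concentrations_to_counts(conc, n_total=6.0)
    assert counts.counts[0] == 1.0
    assert counts.counts[1] == 2.0


def test_all_zero_concentrations_error():
    with pytest.raises(ValueError):
        concentrations_to_counts(np.zeros(3), n_total=10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=12)
)
def test_count_conversion_round_trip_within_one(raw):
    """Eqs converting counts->concentrations->counts are the identity up to
    the final per-species rounding (±1 count)."""
    counts = np.asarray(raw, dtype=float)
    if counts.sum() == 0:
        counts[0] = 1.0
    sc = SpeciesCounts(counts=counts)
    conc = counts_to_concentrations(sc, total_conc=2.0)
    back = concentrations_to_counts(conc, n_total=sc.n_total)
    assert np.all(np.abs(back.counts - counts) <= 1.0)


# -- landing-rate correction ------------------------------------------------


def test_landing_correction_inverse_pair():
    counts = SpeciesCounts(counts=np.array([1000.0, 100.0, 10.0, 5.0, 2.0, 1.0]))
    up = landing_rate_correction(counts, "upscale")
    back = landing_rate_correction(up, "downscale")
    assert np.allclose(back.counts, counts.counts, rtol=1e-12)
    assert (back.counts > 0).tolist() == (counts.counts > 0).tolist()


def test_monomer_efficiency_and_sphere_factor():
    counts = SpeciesCounts(counts=np.array([876.0, 0.0, 0.0, 100.0]))
    up = landing_rate_correction(counts, "upscale")
    assert up.counts[0] == pytest.approx(1000.0)  # /0.876
    assert up.counts[3] == pytest.approx(100.0 * 4 ** (1 / 3))


def test_double_application_guard():
    counts = SpeciesCounts(counts=np.array([10.0]))
    up = landing_rate_correction(counts, "upscale")
    with pytest.raises(ValueError):
        landing_rate_correction(up, "upscale")
    with pytest.raises(ValueError):
        landing_rate_correction(counts, "downscale")


# -- event synthesis --------------------------------------------------------


def test_synthesize_deterministic_and_noiseless_limit():
    counts = SpeciesCounts(counts=np.array([3.0, 2.0]))
    comps = [
        GaussianComponent(mean=42.0, sd=1e-9, area=3, species_index=1),
        GaussianComponent(mean=84.0, sd=1e-9, area=2, species_index=2),
    ]
    a = synthesize_mass_events(counts, comps, seed=5)
    b = synthesize_mass_events(counts, comps, seed=5)
    assert np.array_equal(a.masses, b.masses)
    assert np.allclose(np.sort(a.masses), [42, 42, 42, 84, 84], atol=1e-6)


def test_synthesize_clt_mean():
    n = 100_000
    counts = SpeciesCounts(counts=np.array([float(n)]))
    comps = [GaussianComponent(mean=42.0, sd=8.0, area=n, species_index=1)]
    ev = synthesize_mass_events(counts, comps, seed=0)
    assert abs(ev.masses.mean() - 42.0) < 3 * 8.0 / np.sqrt(n)


def test_synthesize_extrapolated_species_use_largest_sd():
    counts = SpeciesCounts(counts=np.array([0.0, 0.0, 0.0, 0.0, 10.0]))
    comps = [GaussianComponent(mean=42.0, sd=1e-9, area=0, species_index=1)]
    ev = synthesize_mass_events(counts, comps, seed=1)
    assert np.allclose(ev.masses, 5 * 42.0, atol=1e-6)
    with pytest.raises(ValueError):
        synthesize_mass_events(counts, [], seed=1)


def test_histogram_events_layout():
    ev = MassEventList(masses=np.array([42.0, 43.0, 84.0]))
    centers, counts = histogram_events(ev, bin_width=4.0)
    assert counts.sum() == 3
    assert np.allclose(np.diff(centers), 4.0)
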