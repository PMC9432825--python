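"""Synthetic-data generators: presets, determinism, statistical structure."""

import numpy as np
import pytest

from polymerkin.integrate import SolverConfig
from polymerkin.mp import species_index_of_mass
from polymerkin.rates import equal_step_rates
from polymerkin.synthetic import (
    ScenarioPreset,
    fixture_presets,
    generate_mp_dataset,
    generate_scattering_dataset,
)

QUIET = SolverConfig(truncation_warn=False)


@pytest.fixture(scope="module")
def presets():
    return fixture_presets()


def test_presets_validate_and_build(presets):
    assert set(presets) == {
        "atp_hydrolysis_900nM",
        "atp_hydrolysis_2uM_scattering",
        "cation_exchange_AMPPNP",
        "single_state_equal_rates",
        "sm_template_empty_rates",
    }
    for name, p in presets.items():
        if p.has_rates:
            model = p.build_model()
            assert model.n_max == p.n_max


def test_template_preset_has_no_fabricated_rates(presets):
    tpl = presets["sm_template_empty_rates"]
    assert not tpl.has_rates
    with pytest.raises(ValueError, match="template"):
        tpl.build_model()
    assert "transcribe" in tpl.citation


def test_atp_preset_rate_values(presets):
    r = presets["atp_hydrolysis_900nM"].rates
    assert r.k1 == r.k2 == r.k3 == pytest.approx(12.9)
    assert r.km2 == r.km3 == pytest.approx(2.2)
    assert presets["atp_hydrolysis_900nM"].total_conc_uM == pytest.approx(0.9)
    sc = presets["atp_hydrolysis_2uM_scattering"]
    assert sc.n_max == 2000
    assert sc.scattering_points == 1800 and sc.scattering_interval_s == 2.0
    assert sc.scattering_noise_var == pytest.approx(1740.0)


def test_cation_preset_rows(presets):
    r = presets["cation_exchange_AMPPNP"].rates
    assert (r.k1, r.km2) == (pytest.approx(10.6), pytest.approx(5.0))
    assert (r.k4, r.km4) == (pytest.approx(12.9), pytest.approx(2.2))


def _tiny_preset(**over):
    base = ScenarioPreset(
        name="tiny",
        scheme="single_state",
        rates=equal_step_rates(0.0, 0.0),
        n_max=10,
        total_conc_uM=0.5,
        mp_times_min=(1.0, 5.0),
        mp_target_events=2000,
        scattering_points=50,
        scattering_sds=2,
    )
    return base.scaled(**over)


def test_zero_rate_model_yields_pure_monomer_peak():
    ds = generate_mp_dataset(_tiny_preset(mp_peak_sd_kda=2.0), seed=0)
    for ev in ds.events:
        assert np.all(species_index_of_mass(ev.masses) == 1)
        assert abs(ev.masses.mean() - 42.0) < 0.5


def test_same_seed_reproduces_dataset():
    a = generate_mp_dataset(_tiny_preset(), seed=7)
    b = generate_mp_dataset(_tiny_preset(), seed=7)
    for ea, eb in zip(a.events, b.events):
        assert np.array_equal(ea.masses, eb.masses)
    c = generate_mp_dataset(_tiny_preset(), seed=8)
    assert not np.array_equal(a.events[0].masses, c.events[0].masses)


def test_atp_dataset_mass_above_140kda_grows(presets):
    preset = presets["atp_hydrolysis_900nM"].scaled(n_max=120, mp_target_events=6000)
    ds = generate_mp_dataset(preset, seed=3, solver=QUIET)
    fracs = [np.mean(ev.masses > 140.0) for ev in ds.events]
    assert fracs[0] < fracs[-1]
    assert fracs[-1] > 2 * fracs[0]


def test_scattering_dataset_noise_variance():
    preset = _tiny_preset(scattering_points=1800, scattering_noise_var=1740.0)
    ds = generate_scattering_dataset(preset, seed=5)
    resid = ds.trace.signal - ds.clean.signal
    assert np.var(resid) == pytest.approx(1740.0, rel=0.10)
    assert len(ds.trace) == 1800
    # monomer-only truth with a detection floor above 1: pure noise around 0
    assert np.all(ds.clean.signal == 0.0)
    assert abs(resid.mean()) < 3 * np.sqrt(1740.0 / 1800)


def test_zero_noise_scattering_equals_forward_model():
    ds = generate_scattering_dataset(_tiny_preset(scattering_noise_var=0.0), seed=1)
    assert np.array_equal(ds.trace.signal, ds.clean.signal)


def test_low_event_count_warns():
    preset = ScenarioPreset(
        name="few", scheme="single_state", rates=equal_step_rates(0.0, 0.0),
        n_max=10, total_conc_uM=0.5, mp_times_min=(1.0,), mp_target_events=50,
    )
    with pytest.warns(UserWarning, match="unreliable"):
        generate_mp_dataset(preset, seed=0)


def test_event_count_scaling_shrinks_recovery_error():
    """Quadrupling the target event count roughly halves the spread of the
    recovered dimer fraction (Monte Carlo over seeded replicates)."""
    rates = equal_step_rates(5.0, 50.0)  # holds a visible dimer population
    def spread(n_events, seeds):
        vals = []
        for s in seeds:
            p = ScenarioPreset(
                name="se", scheme="single_state", rates=rates, n_max=10,
                total_conc_uM=1.0, mp_times_min=(5.0,), mp_target_events=n_events,
            )
            ds = generate_mp_dataset(p, seed=s)
            idx = species_index_of_mass(ds.events[0].masses)
            vals.append(np.mean(idx == 2))
        return np.std(vals, ddof=1)

    seeds = range(12)
    ratio = spread(1000, seeds) / spread(4000, seeds)
    assert 1.2 < ratio < 3.3  # ideal value 2, generous Monte Carlo slack
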