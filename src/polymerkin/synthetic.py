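"""Ground-truth-known synthetic datasets for the full analysis chain.

The generators invert the analysis: integrate a kinetic model, convert
concentrations to expected detected-particle counts (including the
diffusion-dependent landing bias and the monomer detection efficiency,
applied as independent thinning), draw multinomial event counts, and dress
each event with Gaussian mass-peak noise.  Scattering traces are the
noiseless forward model plus i.i.d. Gaussian noise at the configured
variance.  Every dataset returns the exact generating trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .integrate import DistributionTimeCourse, SolverConfig, integrate_model
from .models import ModelSpec, build_single_state_model, build_two_state_model
from .mp import (
    DiffusionParams,
    GaussianComponent,
    MassEventList,
    MONOMER_DETECTION_EFFICIENCY,
    MONOMER_MASS_KDA,
    SpeciesCounts,
    diffusion_coefficient,
    synthesize_mass_events,
)
from .rates import (
    RateSet,
    atp_hydrolysis_rates,
    cation_exchange_rates,
    equal_step_rates,
)
from .scattering import ScatteringParams, ScatteringTrace, scattering_signal

__all__ = [
    "ScenarioPreset",
    "MPDataset",
    "ScatteringDataset",
    "generate_mp_dataset",
    "generate_scattering_dataset",
    "fixture_presets",
    "default_components",
]

#: Default SD (kDa) of the resolved low-order mass peaks; an assumption —
#: the experimental per-peak SDs are not tabulated.
DEFAULT_PEAK_SD_KDA = 8.0


def default_components(n_fitted: int = 3, sd: float = DEFAULT_PEAK_SD_KDA):
    """Idealized Gaussian components at exact multiples of 42 kDa."""
    return [
        GaussianComponent(mean=i * MONOMER_MASS_KDA, sd=sd, area=0.0, species_index=i)
        for i in range(1, n_fitted + 1)
    ]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named study condition: model, acquisition plan and noise settings."""

    name: str
    scheme: str
    rates: RateSet | None
    n_max: int
    total_conc_uM: float
    mp_times_min: tuple = (1.0, 5.0, 10.0, 15.0)
    mp_target_events: int = 9000
    mp_peak_sd_kda: float = DEFAULT_PEAK_SD_KDA
    scattering_interval_s: float = 2.0
    scattering_points: int = 1800
    scattering_noise_var: float = 1740.0
    scattering_sds: int = 30
    scattering_scale: float = 100.0
    monomer_efficiency: float = MONOMER_DETECTION_EFFICIENCY
    seed: int = 0
    citation: str = ""

    def __post_init__(self):
        if self.mp_target_events <= 0:
            raise ValueError("mp_target_events must be > 0")
        if self.scattering_noise_var < 0 or self.mp_peak_sd_kda < 0:
            raise ValueError("noise scales must be >= 0")
        if self.scattering_points < 1:
            raise ValueError("scattering_points must be >= 1")

    @property
    def has_rates(self) -> bool:
        return self.rates is not None

    def build_model(self) -> ModelSpec:
        if self.rates is None:
            raise ValueError(
                f"preset {self.name!r} is a template: supply rate constants "
                f"({self.citation})"
            )
        if self.scheme == "single_state":
            return build_single_state_model(
                self.rates, self.n_max, total_conc=self.total_conc_uM
            )
        return build_two_state_model(
            self.rates, self.n_max, total_conc=self.total_conc_uM
        )

    def scaled(self, **overrides) -> "ScenarioPreset":
        """Copy with overrides (e.g. smaller n_max for quick runs)."""
        return replace(self, **overrides)


def fixture_presets() -> dict[str, ScenarioPreset]:
    """Named presets mirroring the study conditions.

    ``sm_template_empty_rates`` carries only citations: the Sept/McCammon
    rate-constant tables are not reproduced here and must be supplied by
    the user from the original reference.
    """
    atp = atp_hydrolysis_rates()
    cation = cation_exchange_rates()
    return {
        "atp_hydrolysis_900nM": ScenarioPreset(
            name="atp_hydrolysis_900nM",
            scheme="two_state",
            rates=atp,
            n_max=400,
            total_conc_uM=0.9,
        ),
        "atp_hydrolysis_2uM_scattering": ScenarioPreset(
            name="atp_hydrolysis_2uM_scattering",
            scheme="two_state",
            rates=atp,
            n_max=2000,
            total_conc_uM=2.0,
        ),
        "cation_exchange_AMPPNP": ScenarioPreset(
            name="cation_exchange_AMPPNP",
            scheme="two_state",
            rates=cation,
            n_max=400,
            total_conc_uM=0.9,
        ),
        "single_state_equal_rates": ScenarioPreset(
            name="single_state_equal_rates",
            scheme="single_state",
            rates=equal_step_rates(k=12.9, km=2.2),
            n_max=400,
            total_conc_uM=0.12,
        ),
        "sm_template_empty_rates": ScenarioPreset(
            name="sm_template_empty_rates",
            scheme="single_state",
            rates=None,
            n_max=400,
            total_conc_uM=0.9,
            citation=(
                "Sept & McCammon free-energy rate constants: transcribe from "
                "the original reference / supplement"
            ),
        ),
    }


@dataclass(frozen=True)
class MPDataset:
    """Synthetic MP acquisition series plus its exact generating truth."""

    events: tuple[MassEventList, ...]
    truth: DistributionTimeCourse
    expected_counts: tuple[SpeciesCounts, ...]  # detected-count expectations
    components: tuple[GaussianComponent, ...]
    preset: ScenarioPreset
    seed: int


@dataclass(frozen=True)
class ScatteringDataset:
    trace: ScatteringTrace
    clean: ScatteringTrace
    truth: DistributionTimeCourse
    preset: ScenarioPreset
    seed: int


def detection_weights(
    conc_per_size: np.ndarray,
    params: DiffusionParams | None = None,
    monomer_efficiency: float = MONOMER_DETECTION_EFFICIENCY,
) -> np.ndarray:
    """Unnormalized probability that a detected event is species i.

    Landing rates scale with the species diffusion coefficient, so the
    solution number-concentrations are thinned by D_i / D_monomer; the
    monomer is additionally thinned by its detection efficiency.
    """
    params = params or DiffusionParams()
    sizes = np.arange(1, conc_per_size.size + 1)
    d = diffusion_coefficient(sizes, params)
    w = conc_per_size * (d / params.d_monomer_cm2_s)
    w[0] *= monomer_efficiency
    return w


def generate_mp_dataset(
    preset: ScenarioPreset,
    seed: int | None = None,
    solver: SolverConfig | None = None,
    output_interval_s: float = 30.0,
) -> MPDataset:
    """Synthesize one MP time series (one event list per acquisition time).

    The generating trajectory is integrated on a 30-s output grid covering
    the acquisition plan; event counts at each time point are multinomial
    draws at the target event count, with species probabilities given by
    the landing/detection-thinned number concentrations.
    """
    seed = preset.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = preset.build_model()
    t_end = max(preset.mp_times_min) * 60.0
    t_grid = np.unique(
        np.concatenate(
            [
                np.arange(0.0, t_end + output_interval_s / 2, output_interval_s),
                np.asarray(preset.mp_times_min, dtype=float) * 60.0,
            ]
        )
    )
    truth = integrate_model(model, t_grid, solver)
    components = tuple(default_components(sd=preset.mp_peak_sd_kda))
    events, expected = [], []
    for t_min in preset.mp_times_min:
        conc_A, conc_Ap = truth.at_time(t_min * 60.0)
        w = detection_weights(
            conc_A + conc_Ap, monomer_efficiency=preset.monomer_efficiency
        )
        p = w / w.sum()
        expected_counts = SpeciesCounts(counts=preset.mp_target_events * p)
        n_expected = float(expected_counts.counts.sum())
        if n_expected < 100:
            warnings.warn(
                f"expected only {n_expected:.0f} events at t={t_min} min; "
                "recovery tests are unreliable",
                UserWarning,
                stacklevel=2,
            )
        drawn = rng.multinomial(preset.mp_target_events, p)
        ev = synthesize_mass_events(
            SpeciesCounts(counts=drawn.astype(float)),
            list(components),
            seed=int(rng.integers(2**31)),
            time_label_min=float(t_min),
        )
        events.append(ev)
        expected.append(expected_counts)
    return MPDataset(
        events=tuple(events),
        truth=truth,
        expected_counts=tuple(expected),
        components=components,
        preset=preset,
        seed=seed,
    )


def generate_scattering_dataset(
    preset: ScenarioPreset,
    seed: int | None = None,
    solver: SolverConfig | None = None,
) -> ScatteringDataset:
    """Noiseless forward-model trace plus additive Gaussian noise."""
    seed = preset.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = preset.build_model()
    t_grid = np.arange(preset.scattering_points) * preset.scattering_interval_s
    truth = integrate_model(model, t_grid, solver)
    params = ScatteringParams(
        sds=preset.scattering_sds,
        s=preset.scattering_scale,
        n=preset.n_max,
    )
    clean = scattering_signal(truth, params)
    noise = rng.normal(
        0.0, np.sqrt(preset.scattering_noise_var), size=clean.signal.size
    )
    noisy = ScatteringTrace(
        times=clean.times,
        signal=clean.signal + noise,
        params=params,
        provenance="synthetic",
    )
    return ScatteringDataset(
        trace=noisy, clean=clean, truth=truth, preset=preset, seed=seed
    )
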