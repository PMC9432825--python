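"""Mass-photometry observables: event lists, species counts and the
corrections that map between detected counts and solution concentrations.

A mass-photometry acquisition yields a list of single-particle masses
(kDa).  Counts per oligomeric species come from Gaussian peak areas for the
resolved low-order peaks and from 42-kDa spaced bins above them.  Two
detection biases are corrected multiplicatively: species land on the
measurement surface at rates proportional to their diffusion coefficient
(slower large species are under-counted), and monomers near the detection
limit are found with 87.6% efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MassEventList",
    "GaussianComponent",
    "SpeciesCounts",
    "DiffusionParams",
    "fit_gaussian_mixture",
    "counts_from_events",
    "counts_to_concentrations",
    "concentrations_to_counts",
    "diffusion_coefficient",
    "landing_rate_correction",
    "synthesize_mass_events",
    "histogram_events",
]

MONOMER_MASS_KDA = 42.0
MONOMER_DETECTION_EFFICIENCY = 0.876
BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class MassEventList:
    """Detected particle masses (kDa) from one landing video."""

    masses: np.ndarray
    time_label_min: float | None = None
    dilution_factor: float = 1.0
    video_duration_s: float = 60.0

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        if m.ndim != 1:
            raise ValueError("masses must be 1-D")
        if m.size and (not np.all(np.isfinite(m)) or np.any(m <= 0)):
            raise ValueError("masses must be positive and finite")
        object.__setattr__(self, "masses", m)

    def __len__(self) -> int:
        return self.masses.size

    def to_dataframe(self) -> pd.DataFrame:
        t = np.full(len(self), np.nan if self.time_label_min is None else self.time_label_min)
        return pd.DataFrame({"mass_kDa": self.masses, "time_min": t})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MassEventList":
        df = pd.read_csv(path)
        t = df["time_min"].iloc[0] if "time_min" in df and len(df) else None
        t = None if t is None or pd.isna(t) else float(t)
        return cls(masses=df["mass_kDa"].to_numpy(), time_label_min=t)


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted mass peak: area is the event count under the Gaussian."""

    mean: float  # kDa
    sd: float  # kDa
    area: float  # events
    species_index: int

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass(frozen=True)
class SpeciesCounts:
    """Event counts per oligomeric species i = 1..n (index i-1).

    Counts may be fractional (Gaussian areas, expectation values).  The
    flags record which multiplicative corrections have been applied.
    """

    counts: np.ndarray
    landing_corrected: bool = False
    efficiency_corrected: bool = False

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("counts must be finite and >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n_species(self) -> int:
        return self.counts.size

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.n_species + 1)

    @property
    def n_subunits(self) -> np.ndarray:
        """Subunit-weighted counts N_subunits,i = N_i * i."""
        return self.counts * self.sizes

    @property
    def n_total(self) -> float:
        return float(self.n_subunits.sum())


@dataclass(frozen=True)
class DiffusionParams:
    """Everything needed for species-wise diffusion coefficients.

    Oligomers up to ``sphere_max_i`` subunits are treated as spheres whose
    diffusion coefficient scales with mass^(-1/3) from the monomer value;
    larger species are rigid rods (diameter ``rod_diameter_nm``, length
    i * ``subunit_rise_nm``) with the Tirado-Garcia de la Torre formula.
    """

    d_monomer_cm2_s: float = 7.9e-7
    monomer_mass_kda: float = MONOMER_MASS_KDA
    rod_diameter_nm: float = 7.0
    subunit_rise_nm: float = 2.7
    temperature_k: float = 293.15
    viscosity_pa_s: float = 1e-3
    sphere_max_i: int = 4

    def __post_init__(self):
        for name in (
            "d_monomer_cm2_s", "monomer_mass_kda", "rod_diameter_nm",
            "subunit_rise_nm", "temperature_k", "viscosity_pa_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sphere_max_i < 1:
            raise ValueError("sphere_max_i must be >= 1")


def diffusion_coefficient(i, params: DiffusionParams | None = None) -> np.ndarray | float:
    """Diffusion coefficient (cm² s⁻¹) of an i-mer.

    Sphere scaling D_monomer * i^(-1/3) for i <= sphere_max_i; for larger
    species the rod formula D = k_B T (ln p + v) / (3 π η L) with
    p = L/d and v = 0.312 + 0.565/p - 0.1/p².
    """
    params = params or DiffusionParams()
    i_arr = np.asarray(i)
    if np.any(i_arr < 1):
        raise ValueError("species index must be >= 1")
    scalar = i_arr.ndim == 0
    i_arr = np.atleast_1d(i_arr).astype(float)

    d_sphere = params.d_monomer_cm2_s * i_arr ** (-1.0 / 3.0)

    length_m = i_arr * params.subunit_rise_nm * 1e-9
    p = (i_arr * params.subunit_rise_nm) / params.rod_diameter_nm
    v = 0.312 + 0.565 / p - 0.1 / p**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d_rod_m2 = (
            BOLTZMANN * params.temperature_k * (np.log(p) + v)
            / (3.0 * pi * params.viscosity_pa_s * length_m)
        )
    d_rod = d_rod_m2 * 1e4  # m²/s -> cm²/s

    out = np.where(i_arr <= params.sphere_max_i, d_sphere, d_rod)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# histogramming and mixture fitting


def histogram_events(
    events: MassEventList, bin_width: float = 4.0, mass_range: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_centers, counts) with fixed-width bins (default 4 kDa display)."""
    if mass_range is None:
        hi = events.masses.max() if len(events) else 10 * MONOMER_MASS_KDA
        mass_range = (0.0, float(np.ceil(hi / bin_width) * bin_width + bin_width))
    edges = np.arange(mass_range[0], mass_range[1] + bin_width / 2, bin_width)
    counts, edges = np.histogram(events.masses, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


class MixtureFitError(RuntimeError):
    """Gaussian mixture fit failed; carries residual diagnostics."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


def fit_gaussian_mixture(
    bin_centers: np.ndarray,
    counts: np.ndarray,
    n_components: int,
    monomer_mass_kda: float = MONOMER_MASS_KDA,
    mean_tolerance: float = 0.25,
    sd_bounds: tuple[float, float] = (2.0, 30.0),
    poisson_weights: bool = True,
) -> list[GaussianComponent]:
    """Least-squares fit of a sum of Gaussians to a low-mass histogram.

    Component ``k`` (species ``k+1``) is constrained to mean within
    ±``mean_tolerance`` of (k+1)·monomer mass.  Areas are event counts from
    the analytic Gaussian integral (the fitted amplitude parameter is the
    area; the histogram model multiplies by the bin width).  By default the
    residuals are Poisson-weighted so a small oligomer peak is not swamped
    by counting noise on a peak several hundred times larger; the weights
    come from the fitted model (two-pass Pearson scheme) rather than the
    observed counts, which would bias small peak areas low.
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("histogram too short for a mixture fit")
    if not np.any(y > 0):
        raise MixtureFitError("empty histogram; nothing to fit")
    if n_components < 1 or n_components > 4:
        raise ValueError("n_components must be in 1..4")
    bw = float(np.median(np.diff(x)))

    def model(xx, *theta):
        total = np.zeros_like(xx)
        for k in range(n_components):
            area, mu, sd = theta[3 * k: 3 * k + 3]
            total = total + area * bw / (sd * np.sqrt(2 * pi)) * np.exp(
                -0.5 * ((xx - mu) / sd) ** 2
            )
        return total

    p0, lo, hi = [], [], []
    for k in range(n_components):
        mu0 = (k + 1) * monomer_mass_kda
        sel = np.abs(x - mu0) <= monomer_mass_kda / 2
        guess_area = max(float(y[sel].sum()), 1.0)
        p0 += [guess_area, mu0, 8.0]
        lo += [0.0, mu0 * (1 - mean_tolerance), sd_bounds[0]]
        hi += [np.inf, mu0 * (1 + mean_tolerance), sd_bounds[1]]
    sigma = np.sqrt(np.maximum(y, 1.0)) if poisson_weights else None
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lo, hi), sigma=sigma,
                            maxfev=20000)
        if poisson_weights:
            for _ in range(2):  # Pearson passes: weights from the model
                sigma = np.sqrt(np.maximum(model(x, *popt), 1.0))
                popt, _ = curve_fit(model, x, y, p0=popt, bounds=(lo, hi),
                                    sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        raise MixtureFitError(
            f"mixture fit did not converge: {exc}",
            residual=y - model(x, *p0),
        ) from exc
    comps = [
        GaussianComponent(
            mean=float(popt[3 * k + 1]),
            sd=float(popt[3 * k + 2]),
            area=float(popt[3 * k]),
            species_index=k + 1,
        )
        for k in range(n_components)
    ]
    means = [c.mean for c in comps]
    if any(b <= a for a, b in zip(means, means[1:])):
        raise MixtureFitError("fitted component means are not increasing", None)
    return comps


def species_index_of_mass(masses, bin_width: float = MONOMER_MASS_KDA) -> np.ndarray:
    """Species index by half-open 42-kDa bins [i·42 − 21, i·42 + 21)."""
    return np.floor((np.asarray(masses, dtype=float) + bin_width / 2) / bin_width).astype(int)


def counts_from_events(
    events: MassEventList,
    components: list[GaussianComponent],
    bin_width: float = MONOMER_MASS_KDA,
) -> SpeciesCounts:
    """Species counts: Gaussian areas for fitted species 1..m, half-open
    42-kDa bin occupancy above them."""
    if not components:
        raise ValueError("at least one fitted component is required")
    idx_fitted = sorted(c.species_index for c in components)
    if idx_fitted != list(range(1, len(components) + 1)):
        raise ValueError("components must cover species 1..m without gaps")
    m = len(components)
    idx = species_index_of_mass(events.masses, bin_width)
    idx = idx[idx >= 1]
    n_species = max(int(idx.max()) if idx.size else 0, m)
    counts = np.zeros(n_species)
    for c in components:
        counts[c.species_index - 1] = c.area
    above = idx[idx > m]
    if above.size:
        counts[m:] += np.bincount(above - 1, minlength=n_species)[m:]
    return SpeciesCounts(counts=counts)


# ---------------------------------------------------------------------------
# count <-> concentration bookkeeping


def counts_to_concentrations(counts: SpeciesCounts, total_conc: float) -> np.ndarray:
    """Concentrations [A_i] (µM) from species counts and total actin.

    [A_i]_subunits = total · N_subunits,i / Σ N_subunits,i, then
    [A_i] = [A_i]_subunits / i; total subunit mass is preserved exactly.
    """
    nsub = counts.n_subunits
    total_sub = nsub.sum()
    if total_sub <= 0:
        raise ValueError("zero total subunit count")
    conc_subunits = total_conc * nsub / total_sub
    return conc_subunits / counts.sizes


def concentrations_to_counts(
    conc_A: np.ndarray,
    n_total: float,
    conc_Aprime: np.ndarray | None = None,
) -> SpeciesCounts:
    """Counts from concentrations given the total subunit count N_total.

    Primed and unprimed concentrations are summed per size first (the two
    states are indistinguishable in mass photometry).  Per-species counts
    are N_i = round(N_subunits,i / i) with numpy's round-half-even rule.
    """
    conc = np.asarray(conc_A, dtype=float)
    if conc_Aprime is not None:
        conc = conc + np.asarray(conc_Aprime, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    sizes = np.arange(1, conc.size + 1)
    conc_sub = conc * sizes
    total_sub = conc_sub.sum()
    if total_sub <= 0:
        raise ValueError("all-zero concentrations")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    nsub = n_total * conc_sub / total_sub
    counts = np.round(nsub / sizes)
    return SpeciesCounts(counts=counts)


def landing_rate_correction(
    counts: SpeciesCounts,
    direction: str,
    params: DiffusionParams | None = None,
    monomer_efficiency: float = MONOMER_DETECTION_EFFICIENCY,
) -> SpeciesCounts:
    """Diffusion-based landing-rate (and monomer detection) correction.

    ``upscale`` converts detected counts to solution-representative counts:
    N_i × D_monomer / D_i, and N_1 / monomer_efficiency.  ``downscale`` is
    the exact inverse (solution counts to expected detected counts).  The
    flags on ``counts`` guard against double application.
    """
    params = params or DiffusionParams()
    if direction not in ("upscale", "downscale"):
        raise ValueError("direction must be 'upscale' or 'downscale'")
    if direction == "upscale" and counts.landing_corrected:
        raise ValueError("counts are already landing-rate corrected")
    if direction == "downscale" and not counts.landing_corrected:
        raise ValueError("counts are not landing-rate corrected; cannot downscale")
    d = diffusion_coefficient(counts.sizes, params)
    factor = params.d_monomer_cm2_s / d
    eff = np.ones_like(factor)
    eff[0] = monomer_efficiency
    if direction == "upscale":
        new = counts.counts * factor / eff
    else:
        new = counts.counts / factor * eff
    return SpeciesCounts(
        counts=new,
        landing_corrected=direction == "upscale",
        efficiency_corrected=direction == "upscale",
    )


def synthesize_mass_events(
    counts: SpeciesCounts,
    components: list[GaussianComponent],
    seed: int,
    time_label_min: float | None = None,
) -> MassEventList:
    """Draw a synthetic particle-mass list from species counts.

    Each of the N_i events of species i gets the fitted Gaussian mean of
    that species plus zero-mean Gaussian noise with the fitted SD; species
    beyond the fitted range use i·42 kDa and the SD of the largest fitted
    component.  (The original protocol describes this noise as Poissonian
    while also assigning it the fitted Gaussian SD, which is contradictory;
    Gaussian noise with that SD is what the published histograms show, so
    that is what is implemented.)
    """
    if not components:
        raise ValueError(
            "no fitted components: need at least one to supply a fallback SD"
        )
    by_index = {c.species_index: c for c in components}
    largest = max(components, key=lambda c: c.species_index)
    rng = np.random.default_rng(seed)
    n_events = np.rint(counts.counts).astype(int)
    masses = []
    for i, n in zip(counts.sizes, n_events):
        if n <= 0:
            continue
        comp = by_index.get(int(i))
        mean = comp.mean if comp else i * MONOMER_MASS_KDA
        sd = comp.sd if comp else largest.sd
        masses.append(mean + sd * rng.standard_normal(n))
    all_masses = np.concatenate(masses) if masses else np.empty(0)
    return MassEventList(
        masses=np.clip(all_masses, 1e-6, None), time_label_min=time_label_min
    )
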