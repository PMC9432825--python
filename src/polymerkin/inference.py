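"""Bayesian fitting of kinetic models to mass-photometry and scattering data.

The joint objective assumes Gaussian errors in each data channel j (bulk
light scattering, mass photometry) with a per-channel noise scale σ_j²:

    −ln L = Σ_j [ 2 N_j ln σ_j + N_j ln 2π + Σ_i (y_ij − f_ij(θ))² / (2 σ_j²) ]

where f_ij(θ) is the forward model (ODE integration inside) evaluated at
the data points — histogram bin mid-point counts for mass photometry.
Priors are uninformative: uniform on [0, bound_factor × reference] per rate
constant.  Sampling uses the affine-invariant ensemble sampler with a
differential-evolution / snooker move mixture (80% / 20%).

A Neyman-χ² weighted variant of the objective (per-bin variance equal to
the observed count, floor 1) is available per dataset via ``neyman=True``;
the Gaussian fixed-σ form is the primary objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import emcee
from emcee.autocorr import AutocorrError, integrated_time

__all__ = [
    "FitDataset",
    "LikelihoodConfig",
    "ParameterVector",
    "InferenceResult",
    "joint_neg_log_likelihood",
    "log_prior",
    "make_log_posterior",
    "run_ensemble_mcmc",
    "autocorrelation_time",
    "information_criteria",
    "corner_data",
]

LN_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParameterVector:
    """Ordered fitted parameters with their literature reference values."""

    names: tuple[str, ...]
    references: np.ndarray  # same order; > 0

    def __post_init__(self):
        refs = np.asarray(self.references, dtype=float)
        if len(self.names) != refs.size or refs.size < 1:
            raise ValueError("names and references must align and be non-empty")
        if np.any(refs <= 0):
            raise ValueError("every fitted parameter needs a positive reference")
        object.__setattr__(self, "references", refs)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def dim(self) -> int:
        return len(self.names)


@dataclass
class FitDataset:
    """One data channel: observations y, forward model f(θ), noise scale."""

    name: str
    y: np.ndarray
    forward: object  # callable θ -> prediction aligned with y
    sigma2: float = 1.0
    neyman: bool = False

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class LikelihoodConfig:
    datasets: list[FitDataset]
    diagnostics: dict = field(default_factory=lambda: {"failed_forward": 0})

    @property
    def n_points(self) -> int:
        return int(sum(d.n for d in self.datasets))


def joint_neg_log_likelihood(theta: np.ndarray, cfg: LikelihoodConfig) -> float:
    """Evaluate the joint Gaussian −ln L at θ.

    A failed forward evaluation (exception or non-finite output) counts in
    ``cfg.diagnostics['failed_forward']`` and returns +inf, so the sample
    is rejected rather than crashing the sampler.
    """
    total = 0.0
    for ds in cfg.datasets:
        try:
            f = np.asarray(ds.forward(theta), dtype=float)
        except Exception:
            cfg.diagnostics["failed_forward"] += 1
            return np.inf
        if f.shape != ds.y.shape or not np.all(np.isfinite(f)):
            cfg.diagnostics["failed_forward"] += 1
            return np.inf
        r = ds.y - f
        if ds.neyman:
            var = np.maximum(ds.y, 1.0)
            total += float(np.sum(np.log(var))) + ds.n * LN_2PI
            total += float(np.sum(r * r / (2.0 * var)))
        else:
            total += 2.0 * ds.n * 0.5 * np.log(ds.sigma2) + ds.n * LN_2PI
            total += float(np.sum(r * r)) / (2.0 * ds.sigma2)
    return total


def log_prior(
    theta: np.ndarray,
    params: ParameterVector,
    bound_factor: float = 1e5,
) -> float:
    """Uniform box prior on [0, bound_factor × reference] per component."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != params.dim:
        raise ValueError("theta dimension mismatch")
    upper = bound_factor * params.references
    if np.any(theta < 0) or np.any(theta > upper):
        return -np.inf
    return 0.0


def make_log_posterior(
    cfg: LikelihoodConfig,
    params: ParameterVector,
    bound_factor: float = 1e5,
):
    """Log-posterior callable (flat prior inside the box ⇒ posterior equals
    the log-likelihood there)."""

    def log_post(theta):
        lp = log_prior(theta, params, bound_factor)
        if not np.isfinite(lp):
            return -np.inf
        return lp - joint_neg_log_likelihood(theta, cfg)

    return log_post


# ---------------------------------------------------------------------------
# sampling


@dataclass
class InferenceResult:
    """Chains and diagnostics of one ensemble-MCMC run.

    ``chains`` has shape (steps, walkers, dim); ``log_posterior`` is per
    sample.  AIC/BIC use the maximum sampled log-likelihood.
    """

    chains: np.ndarray
    log_posterior: np.ndarray
    acceptance_fraction: np.ndarray
    tau: np.ndarray
    tau_converged: np.ndarray
    parameter_names: tuple[str, ...]
    seed: int
    move_mix: str
    aic: float | None = None
    bic: float | None = None
    max_log_likelihood: float | None = None

    @property
    def n_steps(self) -> int:
        return self.chains.shape[0]

    def flat(self, burn_in: int = 0) -> np.ndarray:
        if burn_in >= self.n_steps:
            raise ValueError("burn_in exceeds chain length")
        return self.chains[burn_in:].reshape(-1, self.chains.shape[2])

    def credible_interval(
        self, param: int, level: float = 0.95, burn_in: int = 0
    ) -> tuple[float, float]:
        samples = self.flat(burn_in)[:, param]
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(samples, [a, 1.0 - a]))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("chains", data=self.chains)
            fh.create_dataset("log_posterior", data=self.log_posterior)
            fh.create_dataset("acceptance_fraction", data=self.acceptance_fraction)
            fh.create_dataset("tau", data=self.tau)
            fh.create_dataset("tau_converged", data=self.tau_converged.astype(int))
            fh.attrs["parameter_names"] = list(self.parameter_names)
            fh.attrs["seed"] = self.seed
            fh.attrs["move_mix"] = self.move_mix
            for k in ("aic", "bic", "max_log_likelihood"):
                v = getattr(self, k)
                if v is not None:
                    fh.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "InferenceResult":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                chains=fh["chains"][()],
                log_posterior=fh["log_posterior"][()],
                acceptance_fraction=fh["acceptance_fraction"][()],
                tau=fh["tau"][()],
                tau_converged=fh["tau_converged"][()].astype(bool),
                parameter_names=tuple(fh.attrs["parameter_names"]),
                seed=int(fh.attrs["seed"]),
                move_mix=str(fh.attrs["move_mix"]),
                aic=float(fh.attrs["aic"]) if "aic" in fh.attrs else None,
                bic=float(fh.attrs["bic"]) if "bic" in fh.attrs else None,
                max_log_likelihood=(
                    float(fh.attrs["max_log_likelihood"])
                    if "max_log_likelihood" in fh.attrs
                    else None
                ),
            )


def _initial_walkers(
    rng: np.random.Generator,
    center: np.ndarray,
    n_walkers: int,
    radius_frac: float,
    upper: np.ndarray,
) -> np.ndarray:
    """Gaussian ball around the reference values, resampled into the prior."""
    dim = center.size
    init = np.empty((n_walkers, dim))
    for w in range(n_walkers):
        for _ in range(1000):
            x = center * (1.0 + radius_frac * rng.standard_normal(dim))
            if np.all(x >= 0) and np.all(x <= upper):
                init[w] = x
                break
        else:  # pragma: no cover - pathological radius
            init[w] = np.clip(center, 0, upper)
    return init


def run_ensemble_mcmc(
    log_posterior,
    params: ParameterVector,
    n_walkers: int,
    n_steps: int,
    seed: int,
    init: np.ndarray | None = None,
    init_radius_frac: float = 0.01,
    move_mix: str = "de80_snooker20",
    bound_factor: float = 1e5,
    n_data: int | None = None,
) -> InferenceResult:
    """Affine-invariant ensemble MCMC with the DE/snooker move mixture.

    Walkers start in a Gaussian ball (default 1% radius) around the
    literature reference values, never outside the prior box.  Fully
    reproducible under ``seed``.  If ``n_data`` is given, AIC/BIC are
    computed from the maximum sampled log-likelihood (the prior is flat
    inside its box, so the log-posterior equals the log-likelihood there).
    """
    dim = params.dim
    if n_walkers <= 2 * dim:
        raise ValueError("n_walkers must exceed 2 × dim(θ)")
    rng = np.random.default_rng(seed)
    upper = bound_factor * params.references
    if init is None:
        init = _initial_walkers(rng, params.references, n_walkers, init_radius_frac, upper)
    else:
        init = np.asarray(init, dtype=float)
        if init.shape != (n_walkers, dim):
            raise ValueError("init must have shape (n_walkers, dim)")

    if move_mix == "de80_snooker20":
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    elif move_mix == "stretch":
        moves = [(emcee.moves.StretchMove(), 1.0)]
    else:
        raise ValueError(f"unknown move_mix {move_mix!r}")

    sampler = emcee.EnsembleSampler(n_walkers, dim, log_posterior, moves=moves)
    sampler.random_state = np.random.RandomState(seed % 2**32).get_state()
    state = sampler.run_mcmc(init, n_steps, progress=False, skip_initial_state_check=True)
    if np.all(sampler.acceptance_fraction == 0):
        raise RuntimeError(
            "sampler stalled: every proposal was rejected for all walkers"
        )

    chains = sampler.get_chain()  # (steps, walkers, dim)
    logp = sampler.get_log_prob()
    tau, converged = autocorrelation_time(chains)

    max_ll = float(np.max(logp[np.isfinite(logp)]))
    aic = bic = None
    if n_data is not None:
        aic, bic = information_criteria(max_ll, dim, n_data)
    return InferenceResult(
        chains=chains,
        log_posterior=logp,
        acceptance_fraction=sampler.acceptance_fraction,
        tau=tau,
        tau_converged=converged,
        parameter_names=params.names,
        seed=seed,
        move_mix=move_mix,
        aic=aic,
        bic=bic,
        max_log_likelihood=max_ll,
    )


def autocorrelation_time(chains: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integrated autocorrelation time τ per parameter.

    ``chains`` is (steps, walkers, dim) or (steps, dim).  Uses the
    automated-windowing estimator (window c=5) averaged over walkers.  The
    companion boolean array flags parameters whose chain is long enough
    (steps ≥ 50 τ) for the estimate to be trustworthy; degenerate
    (zero-variance) chains are flagged as non-converged with τ = nan.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, None, :]
    if chains.ndim != 3:
        raise ValueError("chains must be (steps, walkers, dim)")
    steps, _, dim = chains.shape
    tau = np.full(dim, np.nan)
    converged = np.zeros(dim, dtype=bool)
    for d in range(dim):
        x = chains[:, :, d]
        if np.allclose(x.std(axis=0), 0.0):
            continue
        try:
            tau[d] = float(integrated_time(x[:, :, None], c=5, tol=0)[0])
        except AutocorrError:  # pragma: no cover - tol=0 should not raise
            continue
        converged[d] = steps >= 50.0 * tau[d]
    return tau, converged


def information_criteria(
    max_log_likelihood: float, k: int, n: int
) -> tuple[float, float]:
    """AIC = 2k − 2 ln L̂ and BIC = k ln N − 2 ln L̂."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= 0:
        raise ValueError("N must be positive")
    aic = 2.0 * k - 2.0 * max_log_likelihood
    bic = k * float(np.log(n)) - 2.0 * max_log_likelihood
    return aic, bic


def corner_data(
    chains: np.ndarray,
    burn_in: int,
    bins: int,
) -> dict:
    """Normalized 1-D and 2-D marginal histograms of the posterior samples.

    Returns ``{"marginals": [(edges, probs), ...], "pairs": {(i, j): (xe,
    ye, H)}}`` with probabilities summing to 1; the density maximum across
    the 2-D planes marks the best-fit (maximum-likelihood) region.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, None, :]
    steps, _, dim = chains.shape
    if burn_in >= steps:
        raise ValueError("burn_in must be smaller than the chain length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    flat = chains[burn_in:].reshape(-1, dim)
    marginals = []
    for d in range(dim):
        h, edges = np.histogram(flat[:, d], bins=bins)
        marginals.append((edges, h / h.sum()))
    pairs = {}
    for i in range(dim):
        for j in range(i + 1, dim):
            H, xe, ye = np.histogram2d(flat[:, i], flat[:, j], bins=bins)
            pairs[(i, j)] = (xe, ye, H / H.sum())
    return {"marginals": marginals, "pairs": pairs}
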