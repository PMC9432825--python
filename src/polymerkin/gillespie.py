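"""Exact stochastic simulation (Gillespie SSA) of the polymerization schemes.

Serves as an independent verification oracle for the mean-field ODEs on
small instances.  Deterministic association rate constants k (µM⁻¹ s⁻¹)
convert to per-pair propensities k/Ω, where Ω (molecules per µM) follows
from the reaction volume; self-association of the monomer uses
k1/Ω · m(m−1) so that the mean-field limit recovers k1[A]².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import ModelSpec

__all__ = ["gillespie_oracle", "omega_from_volume", "SSAEnsemble"]

AVOGADRO = 6.02214076e23
DEFAULT_MOLECULE_CAP = 10_000_000


def omega_from_volume(volume_liters: float) -> float:
    """Molecules per µM of concentration in the given volume."""
    if volume_liters <= 0:
        raise ValueError("volume must be positive")
    return AVOGADRO * volume_liters * 1e-6


@dataclass(frozen=True)
class SSAEnsemble:
    """Counts on a fixed time grid for each run: shape (runs, T, species).

    For the two-state scheme, species axis stacks [A_1..A_n, A'_3..A'_n].
    """

    times: np.ndarray
    counts: np.ndarray
    omega: float
    model: ModelSpec

    def concentrations(self) -> np.ndarray:
        return self.counts / self.omega

    def mean_and_se(self) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble mean concentration and its standard error, (T, species)."""
        c = self.concentrations()
        mean = c.mean(axis=0)
        se = c.std(axis=0, ddof=1) / np.sqrt(c.shape[0])
        return mean, se


@njit(cache=True)
def _ssa_single(m0, t_grid, ka, kd, seed):
    np.random.seed(seed)
    n = m0.shape[0]
    m = m0.copy()
    T = t_grid.shape[0]
    out = np.zeros((T, n), dtype=np.int64)
    t = 0.0
    rec = 0
    a = np.zeros(2 * (n - 1))
    while rec < T:
        # propensities: forward steps then backward steps
        mono = float(m[0])
        a[0] = ka[0] * mono * (mono - 1.0)
        for s in range(1, n - 1):
            a[s] = ka[s] * mono * m[s]
        for s in range(n - 1):
            a[n - 1 + s] = kd[s] * m[s + 1]
        atot = 0.0
        for i in range(a.shape[0]):
            atot += a[i]
        if atot <= 0.0:
            break
        t += -np.log(np.random.random()) / atot
        while rec < T and t_grid[rec] < t:
            out[rec] = m
            rec += 1
        if rec >= T:
            break
        r = np.random.random() * atot
        c = 0.0
        idx = -1
        for i in range(a.shape[0]):
            c += a[i]
            if r < c:
                idx = i
                break
        if idx < 0:
            idx = a.shape[0] - 1
        if idx < n - 1:  # forward step idx: A_{idx+1} + A -> A_{idx+2}
            m[0] -= 1
            m[idx] -= 1
            m[idx + 1] += 1
        else:  # backward step s: A_{s+2} -> A_{s+1} + A
            s = idx - (n - 1)
            m[s + 1] -= 1
            m[s] += 1
            m[0] += 1
    while rec < T:
        out[rec] = m
        rec += 1
    return out


@njit(cache=True)
def _ssa_two(m0, t_grid, ka, kd, k4, km4, ktrans, n, seed):
    np.random.seed(seed)
    dim = 2 * n - 2
    m = m0.copy()
    T = t_grid.shape[0]
    out = np.zeros((T, dim), dtype=np.int64)
    t = 0.0
    rec = 0
    # reactions: n-1 unprimed fwd, n-1 unprimed back, n-2 transitions,
    # n-3 primed fwd, n-2 primed back (incl. A'_3 -> A_2 + A)
    nrx = (n - 1) + (n - 1) + (n - 2) + (n - 3) + (n - 2)
    a = np.zeros(nrx)
    while rec < T:
        mono = float(m[0])
        o = 0
        a[o] = ka[0] * mono * (mono - 1.0)
        for s in range(1, n - 1):
            a[o + s] = ka[s] * mono * m[s]
        o += n - 1
        for s in range(n - 1):
            a[o + s] = kd[s] * m[s + 1]
        o += n - 1
        for i in range(2, n):
            a[o + i - 2] = ktrans * m[i]
        o += n - 2
        for j in range(n - 3):
            a[o + j] = k4 * mono * m[n + j]
        o += n - 3
        for j in range(n - 2):  # A'_{j+3} loses a subunit (j=0: to A_2 + A)
            a[o + j] = km4 * m[n + j]
        atot = 0.0
        for i in range(nrx):
            atot += a[i]
        if atot <= 0.0:
            break
        t += -np.log(np.random.random()) / atot
        while rec < T and t_grid[rec] < t:
            out[rec] = m
            rec += 1
        if rec >= T:
            break
        r = np.random.random() * atot
        c = 0.0
        idx = -1
        for i in range(nrx):
            c += a[i]
            if r < c:
                idx = i
                break
        if idx < 0:
            idx = nrx - 1
        if idx < n - 1:
            m[0] -= 1
            m[idx] -= 1
            m[idx + 1] += 1
        elif idx < 2 * (n - 1):
            s = idx - (n - 1)
            m[s + 1] -= 1
            m[s] += 1
            m[0] += 1
        elif idx < 2 * (n - 1) + (n - 2):
            i = idx - 2 * (n - 1) + 2
            m[i] -= 1
            m[n + i - 2] += 1
        elif idx < 2 * (n - 1) + (n - 2) + (n - 3):
            j = idx - (2 * (n - 1) + (n - 2))
            m[0] -= 1
            m[n + j] -= 1
            m[n + j + 1] += 1
        else:
            j = idx - (2 * (n - 1) + (n - 2) + (n - 3))
            if j == 0:  # A'_3 -> A_2 + A
                m[n] -= 1
                m[1] += 1
                m[0] += 1
            else:
                m[n + j] -= 1
                m[n + j - 1] += 1
                m[0] += 1
    while rec < T:
        out[rec] = m
        rec += 1
    return out


def gillespie_oracle(
    model: ModelSpec,
    t_grid: np.ndarray,
    seed: int,
    copy_numbers: np.ndarray | None = None,
    volume_liters: float | None = None,
    omega: float | None = None,
    n_runs: int = 1,
    molecule_cap: int = DEFAULT_MOLECULE_CAP,
) -> SSAEnsemble:
    """Run the exact SSA over the model's reaction network.

    Either ``copy_numbers`` (integer initial counts in the packed state
    layout) plus a volume/Ω, or a volume/Ω alone (counts are then rounded
    from the model's initial concentrations).  Reproducible under ``seed``;
    run r uses ``seed + r``.
    """
    if omega is None:
        if volume_liters is None:
            raise ValueError("provide omega or volume_liters")
        omega = omega_from_volume(volume_liters)
    if copy_numbers is None:
        copy_numbers = np.rint(model.initial_state() * omega).astype(np.int64)
    else:
        copy_numbers = np.asarray(copy_numbers)
        if not np.issubdtype(copy_numbers.dtype, np.integer):
            raise ValueError("copy_numbers must be integers")
        copy_numbers = copy_numbers.astype(np.int64)
    if copy_numbers.shape != (model.dim,):
        raise ValueError(f"copy_numbers must have shape ({model.dim},)")
    sizes = np.arange(1, model.n_max + 1, dtype=np.int64)
    total = int(sizes @ copy_numbers[: model.n_max])
    if model.scheme == "two_state":
        total += int(np.arange(3, model.n_max + 1) @ copy_numbers[model.n_max:])
    if total > molecule_cap:
        raise ValueError(
            f"{total} molecules exceeds the oracle cap {molecule_cap}; "
            "the SSA oracle is meant for small instances"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    ka, kd = model.step_rate_arrays()
    ka_st = ka / omega  # per-molecule-pair rates
    runs = np.empty((n_runs, t_grid.size, model.dim), dtype=np.int64)
    for r in range(n_runs):
        s = int((seed + r) % 2**31)
        if model.scheme == "single_state":
            runs[r] = _ssa_single(copy_numbers, t_grid, ka_st, kd, s)
        else:
            rt = model.rates
            runs[r] = _ssa_two(
                copy_numbers, t_grid, ka_st, kd,
                rt.k4 / omega, rt.km4, rt.k_trans, model.n_max, s,
            )
    return SSAEnsemble(times=t_grid, counts=runs, omega=omega, model=model)
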