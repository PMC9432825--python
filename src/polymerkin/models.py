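"""Polymerization ODE schemes.

Two mean-field schemes over species ``A_1 .. A_n`` (oligomer of ``i``
subunits, concentrations in µM):

* **single_state** — one linear assembly pathway; dimerization ``k1/km1``,
  trimer ``k2/km2``, tetramer ``k3/km3``, all larger steps ``k4/km4``.
  The top species ``A_n`` is absorbing (no flux to ``n+1``).

* **two_state** — oligomers with ``i >= 3`` may irreversibly transition
  (rate ``k_trans``) into a kinetically distinct primed state ``A'_i`` with
  its own elongation rates ``k4/km4``.  The unprimed pathway uses ``k1/km1``,
  ``k2/km2`` and ``k3/km3`` for every step above the trimer.  The primed
  trimer dissociates back into ``A_2 + A`` at ``km4``; otherwise primed
  species only (dis)associate within the primed pathway.

State packing: single_state is ``y[0..n-1] = [A_1..A_n]``; two_state appends
``[A'_3..A'_n]`` giving dimension ``2n - 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import RateSet, RateValidationError

try:  # pragma: no cover - numba is a hard dependency, guard is defensive
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "ModelSpec",
    "ModelValidationError",
    "build_single_state_model",
    "build_two_state_model",
    "monomer_initial_distribution",
]


class ModelValidationError(ValueError):
    """A model specification violates a precondition."""


def monomer_initial_distribution(total_conc: float, n_max: int) -> np.ndarray:
    """All actin starts as free monomer."""
    y0 = np.zeros(n_max)
    y0[0] = total_conc
    return y0


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified polymerization model ready for integration."""

    scheme: str  # "single_state" | "two_state"
    rates: RateSet
    n_max: int
    total_conc: float  # µM of subunits
    initial_A: np.ndarray = field(compare=False)  # length n_max, µM
    initial_Aprime: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.scheme not in ("single_state", "two_state"):
            raise ModelValidationError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "single_state":
            if self.n_max < 5:
                raise ModelValidationError(
                    "single_state requires n_max >= 5 (the scheme distinguishes "
                    "steps up to the tetramer)"
                )
            if self.rates.k_trans != 0.0:
                raise ModelValidationError("single_state requires k_trans == 0")
        else:
            if self.n_max < 4:
                raise ModelValidationError("two_state requires n_max >= 4")
        init_A = np.asarray(self.initial_A, dtype=float)
        if init_A.shape != (self.n_max,):
            raise ModelValidationError(
                f"initial_A must have length n_max={self.n_max}"
            )
        if np.any(init_A < 0):
            raise ModelValidationError("initial distribution must be non-negative")
        object.__setattr__(self, "initial_A", init_A)
        sizes = np.arange(1, self.n_max + 1, dtype=float)
        mass = float(sizes @ init_A)
        if self.scheme == "two_state":
            if self.initial_Aprime is None:
                ip = np.zeros(self.n_max - 2)
            else:
                ip = np.asarray(self.initial_Aprime, dtype=float)
                if ip.shape != (self.n_max - 2,):
                    raise ModelValidationError(
                        "initial_Aprime must have length n_max - 2 (sizes 3..n)"
                    )
                if np.any(ip < 0):
                    raise ModelValidationError(
                        "initial distribution must be non-negative"
                    )
            object.__setattr__(self, "initial_Aprime", ip)
            mass += float(np.arange(3, self.n_max + 1, dtype=float) @ ip)
        elif self.initial_Aprime is not None:
            raise ModelValidationError("single_state takes no primed species")
        if self.total_conc <= 0:
            raise ModelValidationError("total_conc must be positive")
        if abs(mass - self.total_conc) > 1e-9 * self.total_conc:
            raise ModelValidationError(
                f"initial subunit mass {mass} inconsistent with "
                f"total_conc {self.total_conc} (rel. tol 1e-9)"
            )

    # -- packed state ------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.n_max if self.scheme == "single_state" else 2 * self.n_max - 2

    def initial_state(self) -> np.ndarray:
        if self.scheme == "single_state":
            return self.initial_A.copy()
        return np.concatenate([self.initial_A, self.initial_Aprime])

    def split_state(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split packed state(s) into (A, A') blocks of width n_max each.

        Works on a single state vector or on a (T, dim) trajectory.  The
        primed block is zero-padded at sizes 1 and 2 (which do not exist).
        """
        y = np.atleast_2d(y)
        n = self.n_max
        A = y[:, :n]
        Ap = np.zeros_like(A)
        if self.scheme == "two_state":
            Ap[:, 2:] = y[:, n:]
        return A, Ap

    def step_rate_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-step association/dissociation rates for the unprimed pathway.

        Index ``s`` (0-based) is the step ``A_{s+1} + A -> A_{s+2}``.
        """
        r = self.rates
        n = self.n_max
        ka = np.empty(n - 1)
        kd = np.empty(n - 1)
        if self.scheme == "single_state":
            upper_a, upper_d = r.k4, r.km4
            third_a, third_d = r.k3, r.km3
        else:
            upper_a, upper_d = r.k3, r.km3
            third_a, third_d = r.k3, r.km3
        ka[:] = upper_a
        kd[:] = upper_d
        ka[0], kd[0] = r.k1, r.km1
        if n >= 3:
            ka[1], kd[1] = r.k2, r.km2
        if n >= 4:
            ka[2], kd[2] = third_a, third_d
        return ka, kd

    def rhs(self):
        """Return ``f(t, y)`` evaluating the scheme's right-hand side."""
        ka, kd = self.step_rate_arrays()
        if self.scheme == "single_state":
            return lambda t, y: _rhs_single(y, ka, kd)
        r = self.rates
        return lambda t, y: _rhs_two(y, ka, kd, r.k4, r.km4, r.k_trans, self.n_max)

    def jacobian(self):
        """Return ``J(t, y)`` with ``J[i, j] = d f_i / d y_j`` (dense)."""
        ka, kd = self.step_rate_arrays()
        if self.scheme == "single_state":
            return lambda t, y: _jac_single(y, ka, kd)
        r = self.rates
        return lambda t, y: _jac_two(y, ka, kd, r.k4, r.km4, r.k_trans, self.n_max)


# ---------------------------------------------------------------------------
# compiled right-hand sides


@njit(cache=True)
def _rhs_single(y, ka, kd):
    n = y.shape[0]
    A = y[0]
    dy = np.zeros(n)
    # step s (0-based): A_{s+1} + A <-> A_{s+2}; J[s] net forward flux
    acc = 0.0
    prev = ka[0] * A * y[0] - kd[0] * y[1]  # dimerization flux
    dy[0] = -2.0 * prev
    for s in range(1, n - 1):
        J = ka[s] * A * y[s] - kd[s] * y[s + 1]
        acc += J
        dy[s] = prev - J
        prev = J
    dy[n - 1] = prev
    dy[0] -= acc
    return dy


@njit(cache=True)
def _rhs_two(y, ka, kd, k4, km4, ktrans, n):
    # y[:n] = A_1..A_n ; y[n:] = A'_3..A'_n
    dy = np.zeros(2 * n - 2)
    A = y[0]
    acc = 0.0
    prev = ka[0] * A * y[0] - kd[0] * y[1]
    dy[0] = -2.0 * prev
    for s in range(1, n - 1):
        J = ka[s] * A * y[s] - kd[s] * y[s + 1]
        acc += J
        dy[s] = prev - J
        prev = J
    dy[n - 1] = prev
    dy[0] -= acc
    # transitions A_i -> A'_i for i >= 3
    for i in range(2, n):
        T = ktrans * y[i]
        dy[i] -= T
        dy[n + i - 2] += T
    # primed pathway: z[j] = A'_{j+3}, j = 0..n-3
    z0 = y[n]
    out3 = km4 * z0  # A'_3 -> A_2 + A
    dy[0] += out3
    dy[1] += out3
    dy[n] -= out3
    accp = 0.0
    prevp = 0.0
    for j in range(0, n - 3):
        Jp = k4 * A * y[n + j] - km4 * y[n + j + 1]
        accp += Jp
        dy[n + j] += prevp - Jp
        prevp = Jp
    dy[2 * n - 3] += prevp
    dy[0] -= accp
    return dy


@njit(cache=True)
def _jac_single(y, ka, kd):
    n = y.shape[0]
    A = y[0]
    jac = np.zeros((n, n))
    # contribution of step flux J[s] = ka[s]*A*y[s] - kd[s]*y[s+1]
    # dJ[s]/dA: 2*ka[0]*A for s=0 else ka[s]*y[s]; dJ[s]/dy[s] (s>=1): ka[s]*A;
    # dJ[s]/dy[s+1]: -kd[s]
    for s in range(n - 1):
        if s == 0:
            dA = 2.0 * ka[0] * A
        else:
            dA = ka[s] * y[s]
        w0 = -2.0 if s == 0 else -1.0
        # row for species s+2 gains +J[s]; row for species s+1 loses J[s]
        # (for s>=1); monomer row gets w0 * J[s]
        jac[0, 0] += w0 * dA
        jac[s + 1, 0] += dA
        if s >= 1:
            jac[s, 0] -= dA
            v = ka[s] * A
            jac[0, s] += w0 * v
            jac[s + 1, s] += v
            jac[s, s] -= v
        d = -kd[s]
        jac[0, s + 1] += w0 * d
        jac[s + 1, s + 1] += d
        if s >= 1:
            jac[s, s + 1] -= d
    return jac


@njit(cache=True)
def _jac_two(y, ka, kd, k4, km4, ktrans, n):
    m = 2 * n - 2
    A = y[0]
    jac = np.zeros((m, m))
    for s in range(n - 1):
        if s == 0:
            dA = 2.0 * ka[0] * A
        else:
            dA = ka[s] * y[s]
        w0 = -2.0 if s == 0 else -1.0
        jac[0, 0] += w0 * dA
        jac[s + 1, 0] += dA
        if s >= 1:
            jac[s, 0] -= dA
            v = ka[s] * A
            jac[0, s] += w0 * v
            jac[s + 1, s] += v
            jac[s, s] -= v
        d = -kd[s]
        jac[0, s + 1] += w0 * d
        jac[s + 1, s + 1] += d
        if s >= 1:
            jac[s, s + 1] -= d
    for i in range(2, n):
        jac[i, i] -= ktrans
        jac[n + i - 2, i] += ktrans
    # A'_3 -> A_2 + A
    jac[0, n] += km4
    jac[1, n] += km4
    jac[n, n] -= km4
    # primed chain fluxes Jp[j] = k4*A*z[j] - km4*z[j+1]
    for j in range(0, n - 3):
        zj = n + j
        dA = k4 * y[zj]
        v = k4 * A
        d = -km4
        # monomer loses Jp
        jac[0, 0] -= dA
        jac[0, zj] -= v
        jac[0, zj + 1] -= d
        # source species loses Jp
        jac[zj, 0] -= dA
        jac[zj, zj] -= v
        jac[zj, zj + 1] -= d
        # product species gains Jp
        jac[zj + 1, 0] += dA
        jac[zj + 1, zj] += v
        jac[zj + 1, zj + 1] += d
    return jac


# ---------------------------------------------------------------------------
# builders


def _resolve_initial(
    n_max: int,
    total_conc: float | None,
    initial: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    if initial is None:
        if total_conc is None:
            raise ModelValidationError(
                "either total_conc or an initial distribution is required"
            )
        return total_conc, monomer_initial_distribution(total_conc, n_max)
    initial = np.asarray(initial, dtype=float)
    mass = float(np.arange(1, n_max + 1) @ initial)
    if total_conc is None:
        total_conc = mass
    return total_conc, initial


def build_single_state_model(
    rates: RateSet,
    n_max: int,
    total_conc: float | None = None,
    initial: np.ndarray | None = None,
) -> ModelSpec:
    """Single assembly pathway (kinetic scheme 1).

    The monomer equation carries the stoichiometric factor 2 on the
    dimerization flux; species ``n`` has no outflux to ``n+1``.
    """
    if rates.k_trans != 0.0:
        raise RateValidationError("single-state scheme requires k_trans == 0")
    total_conc, initial = _resolve_initial(n_max, total_conc, initial)
    return ModelSpec(
        scheme="single_state",
        rates=rates,
        n_max=n_max,
        total_conc=total_conc,
        initial_A=initial,
    )


def build_two_state_model(
    rates: RateSet,
    n_max: int,
    total_conc: float | None = None,
    initial: np.ndarray | None = None,
    initial_primed: np.ndarray | None = None,
) -> ModelSpec:
    """Two-state scheme (kinetic scheme 2) with irreversible transition
    ``A_i -> A'_i`` for ``i >= 3`` at rate ``k_trans``.

    By default all species start in the unprimed (non-transitioned) state.
    """
    explicit_total = total_conc is not None
    total_conc, initial = _resolve_initial(n_max, total_conc, initial)
    if initial_primed is not None and not explicit_total:
        total_conc += float(np.arange(3, n_max + 1) @ np.asarray(initial_primed, float))
    return ModelSpec(
        scheme="two_state",
        rates=rates,
        n_max=n_max,
        total_conc=total_conc,
        initial_A=initial,
        initial_Aprime=initial_primed,
    )
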