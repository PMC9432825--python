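"""Unit and property tests for the ODE schemes, integrator and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polymerkin as pk
from polymerkin.integrate import SolverConfig, TruncationWarning
from polymerkin.metrics import equilibrium_single_state
from polymerkin.models import ModelValidationError


def dimer_equilibrium_monomer(k1, km1, total):
    """Closed-form free monomer of the pure monomer-dimer system:
    [A] + 2 (k1/km1)[A]^2 = total."""
    K = k1 / km1
    return (-1.0 + np.sqrt(1.0 + 8.0 * K * total)) / (4.0 * K)


def test_zero_rates_null_dynamics(quiet_solver):
    r = pk.RateSet(k1=0, k2=0, k3=0, k4=0, km1=0, km2=0, km3=0, km4=0)
    init = np.zeros(10)
    init[0], init[2], init[7] = 0.2, 0.1, 0.05
    m = pk.build_single_state_model(r, 10, initial=init)
    assert np.allclose(m.rhs()(0.0, m.initial_state()), 0.0)
    d = pk.integrate_model(m, np.linspace(0, 100, 5), quiet_solver)
    assert np.allclose(d.conc_A, init[None, :])


def test_monomer_dimer_equilibrium_matches_quadratic(quiet_solver):
    r = pk.RateSet(k1=5.0, k2=0.0, k3=0.0, k4=0.0,
                   km1=2.0, km2=1.0, km3=1.0, km4=1.0)
    m = pk.build_single_state_model(r, 6, total_conc=1.0)
    d = pk.integrate_model(m, np.array([0.0, 500.0]), quiet_solver)
    a = dimer_equilibrium_monomer(5.0, 2.0, 1.0)
    assert d.conc_A[-1, 0] == pytest.approx(a, rel=1e-6)
    assert d.conc_A[-1, 1] == pytest.approx(5.0 / 2.0 * a**2, rel=1e-6)
    assert np.all(d.conc_A[-1, 2:] < 1e-12)


def test_equal_rate_steady_state_is_geometric(equal_rates):
    conc = equilibrium_single_state(equal_rates, 0.12, 60)
    ratios = conc[1:] / conc[:-1]
    expected = (equal_rates.k4 / equal_rates.km4) * conc[0]
    assert np.allclose(ratios[3:], expected, rtol=1e-9)
    # fixed point of the scheme-1 RHS
    m = pk.build_single_state_model(equal_rates, 60, total_conc=0.12)
    assert np.max(np.abs(m.rhs()(0.0, conc))) < 1e-9


def test_equilibrium_reduces_to_dimer_closed_form():
    r = pk.RateSet(k1=5.0, k2=1.0, k3=1.0, k4=1.0,
                   km1=2.0, km2=1.0, km3=1.0, km4=1.0)
    conc = equilibrium_single_state(r, 1.0, 2)
    a = dimer_equilibrium_monomer(5.0, 2.0, 1.0)
    assert conc[0] == pytest.approx(a, rel=1e-9)


def test_long_integration_converges_to_equilibrium(equal_rates, quiet_solver):
    m = pk.build_single_state_model(equal_rates, 30, total_conc=0.1)
    d = pk.integrate_model(m, np.array([0.0, 5e4]), quiet_solver)
    eq = equilibrium_single_state(equal_rates, 0.1, 30)
    assert np.allclose(d.conc_A[-1], eq, rtol=1e-6, atol=1e-15)


def test_scheme_reduction_k_trans_zero(quiet_solver, minute_grid):
    """Two-state dynamics with the transition off equal the single-state
    scheme with matched stepwise rates, and the primed pool stays empty."""
    base = pk.RateSet(k1=12.9, k2=12.9, k3=12.9, k4=11.6,
                      km1=1e4, km2=2.2, km3=2.2, km4=1.4, k_trans=0.0)
    m2 = pk.build_two_state_model(base, 60, total_conc=0.5)
    # matched single-state: every step above the trimer uses k3/km3
    matched = base.with_(k4=base.k3, km4=base.km3)
    m1 = pk.build_single_state_model(matched, 60, total_conc=0.5)
    d2 = pk.integrate_model(m2, minute_grid, quiet_solver)
    d1 = pk.integrate_model(m1, minute_grid, quiet_solver)
    assert np.all(d2.conc_Aprime == 0.0)
    assert np.max(np.abs(d2.conc_A - d1.conc_A)) < 10 * 1e-8 * 0.5


def test_fast_transition_drains_unprimed_oligomers(quiet_solver):
    r = pk.RateSet(k1=1.0, k2=1.0, k3=1.0, k4=1.0,
                   km1=0.1, km2=0.1, km3=0.1, km4=1e-3, k_trans=1e4)
    m = pk.build_two_state_model(r, 12, total_conc=1.0)
    d = pk.integrate_model(m, np.array([0.0, 2000.0]), quiet_solver)
    unprimed_oligomers = d.conc_A[-1, 2:].sum()
    primed = d.conc_Aprime[-1].sum()
    assert unprimed_oligomers < 1e-6 * primed


@settings(deadline=None, max_examples=12, derandomize=True)
@given(
    km1=st.floats(0.5, 1e5),
    k_trans=st.floats(0.0, 2.0),
    conc=st.floats(0.05, 2.0),
)
def test_mass_conservation_property(km1, k_trans, conc):
    """Total subunit concentration is conserved to 1e-6 relative along any
    two-state trajectory (the integrator enforces it and would raise)."""
    r = pk.RateSet(k1=12.9, k2=12.9, k3=12.9, k4=11.6,
                   km1=km1, km2=2.2, km3=2.2, km4=1.4, k_trans=k_trans)
    m = pk.build_two_state_model(r, 25, total_conc=conc)
    d = pk.integrate_model(m, np.linspace(0.0, 600.0, 11),
                           SolverConfig(truncation_warn=False))
    rel = np.max(np.abs(d.subunit_mass() - conc)) / conc
    assert rel <= 1e-6


def test_analytic_jacobians_match_finite_differences():
    # moderate rate magnitudes keep finite-difference roundoff well below
    # the comparison tolerance
    rng = np.random.default_rng(0)
    r = pk.RateSet(k1=12.9, k2=9.0, k3=7.0, k4=11.6,
                   km1=25.0, km2=2.2, km3=3.3, km4=1.4, k_trans=0.4)
    m1 = pk.build_single_state_model(
        r.with_(k_trans=0.0, interpretation="custom"), 8, total_conc=1.0
    )
    _check_jac(m1, rng)
    m2 = pk.build_two_state_model(r, 8, total_conc=1.0)
    _check_jac(m2, rng)


def _check_jac(model, rng):
    y = rng.uniform(0.01, 0.5, model.dim)
    f, jac = model.rhs(), model.jacobian()
    J = jac(0.0, y)
    eps = 1e-7
    for j in range(model.dim):
        dy = np.zeros(model.dim)
        dy[j] = eps
        col = (f(0.0, y + dy) - f(0.0, y - dy)) / (2 * eps)
        assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-6)


def test_validation_errors():
    ok = pk.equal_step_rates(1.0, 1.0)
    with pytest.raises(ModelValidationError):
        pk.build_single_state_model(ok, 4, total_conc=1.0)  # n_max < 5
    with pytest.raises(ModelValidationError):
        pk.build_single_state_model(ok, 10, initial=-np.ones(10))
    with pytest.raises(ModelValidationError):
        pk.ModelSpec(scheme="single_state", rates=ok, n_max=10,
                     total_conc=2.0, initial_A=np.ones(10) * 0.01)  # mass mismatch
    m = pk.build_single_state_model(ok, 10, total_conc=1.0)
    with pytest.raises(ValueError):
        pk.integrate_model(m, np.array([0.0, 10.0, 5.0]))  # not increasing


def test_truncation_warning_fires(equal_rates):
    # strongly super-critical: mass piles into the absorbing top species
    r = equal_rates.with_(km1=0.01, km2=0.01, km3=0.01, km4=0.01)
    m = pk.build_single_state_model(r, 6, total_conc=1.0)
    with pytest.warns(TruncationWarning):
        pk.integrate_model(m, np.array([0.0, 50.0]))


def test_trajectory_export_layout(tmp_path, atp_rates, quiet_solver):
    m = pk.build_two_state_model(atp_rates, 6, total_conc=0.5)
    d = pk.integrate_model(m, np.array([0.0, 30.0]), quiet_solver)
    path = tmp_path / "traj.csv"
    d.to_csv(path)
    header = path.read_text().splitlines()[0].split(",")
    assert header[:3] == ["time_s", "A_1", "A_2"]
    assert header[-1] == "Ap_6" and "Ap_3" in header


# -- filament metrics -------------------------------------------------------


def _dist_from_rows(rows, n_max, scheme="single_state"):
    rates = pk.equal_step_rates(0.0, 0.0)
    rows = np.asarray(rows, dtype=float)
    total = float(rows[0] @ np.arange(1, n_max + 1))
    model = pk.ModelSpec(scheme=scheme, rates=rates, n_max=n_max,
                         total_conc=total, initial_A=rows[0])
    times = np.arange(rows.shape[0], dtype=float)
    return pk.DistributionTimeCourse(
        times=times, conc_A=rows, conc_Aprime=np.zeros_like(rows), model=model
    )


def test_metrics_all_monomer_and_all_200mer():
    mono = np.zeros(250)
    mono[0] = 1.0
    met = pk.filament_metrics(_dist_from_rows([mono], 250))
    assert met["frac_mass_above_140kDa"].iloc[0] == 0.0
    assert met["frac_mass_above_150mers"].iloc[0] == 0.0
    big = np.zeros(250)
    big[199] = 0.01
    met = pk.filament_metrics(_dist_from_rows([big], 250))
    assert met["frac_mass_above_140kDa"].iloc[0] == 1.0
    assert met["frac_mass_above_150mers"].iloc[0] == 1.0
    assert met["mean_length"].iloc[0] == pytest.approx(200.0)


def test_metrics_dimer_tetramer_split():
    """Half the mass in dimers (84 kDa), half in tetramers (168 kDa)."""
    row = np.zeros(10)
    row[1] = 0.25  # 0.5 µM subunits
    row[3] = 0.125  # 0.5 µM subunits
    met = pk.filament_metrics(_dist_from_rows([row], 10))
    assert met["frac_mass_above_140kDa"].iloc[0] == pytest.approx(0.5)
    assert met["frac_mass_above_150mers"].iloc[0] == 0.0


def test_metrics_zero_mass_errors():
    with pytest.raises(ValueError):
        pk.filament_metrics(_dist_from_rows([np.zeros(10)], 10))


def test_equal_rate_equilibrium_has_almost_no_megadalton_mass(equal_rates):
    """At sub-critical actin (120 nM) the isodesmic steady state keeps less
    than 1% of mass in species of 1 MDa and above (>= 24-mers)."""
    conc = equilibrium_single_state(equal_rates, 0.12, 400)
    sizes = np.arange(1, 401)
    mass = conc * sizes
    assert mass[23:].sum() / mass.sum() < 0.01
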