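"""Likelihood arithmetic, priors, ensemble sampling and diagnostics."""

import numpy as np
import pytest

from polymerkin.inference import (
    FitDataset,
    LikelihoodConfig,
    ParameterVector,
    autocorrelation_time,
    corner_data,
    information_criteria,
    joint_neg_log_likelihood,
    log_prior,
    run_ensemble_mcmc,
)

LN_2PI = np.log(2 * np.pi)


def _cfg(y, f, sigma2=1.0, neyman=False):
    return LikelihoodConfig(
        datasets=[FitDataset(name="d", y=y, forward=f, sigma2=sigma2, neyman=neyman)]
    )


def test_zero_residuals_reduce_to_constant_term():
    y = np.array([1.0, 2.0, 3.0])
    cfg = _cfg(y, lambda th: y)
    val = joint_neg_log_likelihood(np.array([0.0]), cfg)
    assert val == pytest.approx(3 * LN_2PI)  # ≈ 5.5138
    assert val == pytest.approx(5.514, abs=1e-3)


def test_residual_term_scales_quadratically():
    y = np.zeros(4)
    r = np.array([1.0, -2.0, 0.5, 1.5])
    base = joint_neg_log_likelihood(None, _cfg(y, lambda th: r)) - 4 * LN_2PI
    doubled = joint_neg_log_likelihood(None, _cfg(y, lambda th: 2 * r)) - 4 * LN_2PI
    assert doubled == pytest.approx(4 * base)


def test_two_datasets_add():
    y1, y2 = np.array([1.0, 2.0]), np.array([0.0, 1.0, 2.0])
    f1, f2 = (lambda th: y1 + 0.5), (lambda th: y2 - 1.0)
    joint = LikelihoodConfig(
        datasets=[
            FitDataset(name="a", y=y1, forward=f1, sigma2=2.0),
            FitDataset(name="b", y=y2, forward=f2, sigma2=3.0),
        ]
    )
    v1 = joint_neg_log_likelihood(None, _cfg(y1, f1, sigma2=2.0))
    v2 = joint_neg_log_likelihood(None, _cfg(y2, f2, sigma2=3.0))
    assert joint_neg_log_likelihood(None, joint) == pytest.approx(v1 + v2)


def test_fixed_sigma_reduces_to_weighted_least_squares():
    """With σ² fixed, −lnL is the residual quadratic plus an analytic
    constant 2N lnσ + N ln2π."""
    y = np.arange(5.0)
    sigma2 = 1740.0
    r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    val = joint_neg_log_likelihood(None, _cfg(y, lambda th: y - r, sigma2=sigma2))
    const = 2 * 5 * 0.5 * np.log(sigma2) + 5 * LN_2PI
    assert val == pytest.approx(const + (r**2).sum() / (2 * sigma2))


def test_neyman_variant_uses_per_bin_variance():
    y = np.array([100.0, 4.0, 0.0])
    f = y + np.array([10.0, 2.0, 1.0])
    val = joint_neg_log_likelihood(None, _cfg(y, lambda th: f, neyman=True))
    var = np.array([100.0, 4.0, 1.0])
    expected = np.log(var).sum() + 3 * LN_2PI + (100 / 200 + 4 / 8 + 1 / 2)
    assert val == pytest.approx(expected)


def test_failed_forward_maps_to_inf_with_counter():
    def bad(th):
        raise FloatingPointError("ODE blew up")

    cfg = _cfg(np.ones(3), bad)
    assert joint_neg_log_likelihood(None, cfg) == np.inf
    nan_cfg = _cfg(np.ones(3), lambda th: np.array([1.0, np.nan, 1.0]))
    assert joint_neg_log_likelihood(None, nan_cfg) == np.inf
    assert nan_cfg.diagnostics["failed_forward"] == 1


def test_prior_box():
    pv = ParameterVector(names=("a", "b"), references=np.array([2.0, 10.0]))
    assert log_prior(np.array([2.0, 10.0]), pv) == 0.0
    assert log_prior(np.array([-1e-9, 1.0]), pv) == -np.inf
    eps = 1e-6
    assert log_prior(np.array([2e5 - eps, 1.0]), pv) == 0.0
    assert log_prior(np.array([2e5 + eps, 1.0]), pv) == -np.inf
    with pytest.raises(ValueError):
        ParameterVector(names=("a",), references=np.array([0.0]))


def test_gaussian_target_moments():
    """Known-target calibration: the ensemble sampler reproduces the mean
    and covariance of an anisotropic 2-D Gaussian."""
    cov = np.array([[1.0, 0.4], [0.4, 0.5]])
    prec = np.linalg.inv(cov)
    mu = np.array([3.0, 5.0])

    def logp(th):
        d = th - mu
        return -0.5 * d @ prec @ d

    pv = ParameterVector(names=("x", "y"), references=mu)
    res = run_ensemble_mcmc(logp, pv, n_walkers=32, n_steps=3000, seed=4,
                            init_radius_frac=0.3)
    flat = res.flat(burn_in=500)
    assert np.allclose(flat.mean(axis=0), mu, rtol=0.05)
    assert np.allclose(np.cov(flat.T), cov, rtol=0.35, atol=0.05)


def test_chains_bitwise_deterministic_and_invariant_to_constant_shift():
    pv = ParameterVector(names=("x",), references=np.array([1.0]))

    def logp(th):
        return -0.5 * float((th[0] - 1.0) ** 2)

    def logp_shift(th):
        return logp(th) + 123.456

    a = run_ensemble_mcmc(logp, pv, n_walkers=8, n_steps=200, seed=9)
    b = run_ensemble_mcmc(logp, pv, n_walkers=8, n_steps=200, seed=9)
    c = run_ensemble_mcmc(logp_shift, pv, n_walkers=8, n_steps=200, seed=9)
    assert np.array_equal(a.chains, b.chains)
    assert np.array_equal(a.chains, c.chains)  # posterior shape unchanged
    d = run_ensemble_mcmc(logp, pv, n_walkers=8, n_steps=200, seed=10)
    assert not np.array_equal(a.chains, d.chains)


def test_walkers_must_exceed_twice_dim():
    pv = ParameterVector(names=("x", "y"), references=np.ones(2))
    with pytest.raises(ValueError):
        run_ensemble_mcmc(lambda th: 0.0, pv, n_walkers=4, n_steps=10, seed=0)


def test_autocorrelation_white_noise_and_ar1():
    rng = np.random.default_rng(1)
    white = rng.standard_normal((20000, 4, 1))
    tau, ok = autocorrelation_time(white)
    assert tau[0] == pytest.approx(1.0, rel=0.2)
    assert ok[0]
    phi = 0.9
    n = 40000
    ar = np.empty((n, 2, 1))
    for w in range(2):
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + e[t]
        ar[:, w, 0] = x
    tau, ok = autocorrelation_time(ar)
    assert tau[0] == pytest.approx((1 + phi) / (1 - phi), rel=0.25)
    assert ok[0]


def test_autocorrelation_degenerate_chain_flagged():
    const = np.ones((500, 3, 2))
    tau, ok = autocorrelation_time(const)
    assert np.all(np.isnan(tau))
    assert not ok.any()


def test_information_criteria_arithmetic():
    aic, _ = information_criteria(0.0, k=9, n=100)
    assert aic == 18.0
    _, bic = information_criteria(0.0, k=9, n=int(round(np.exp(9))))
    assert bic == pytest.approx(81.0, rel=1e-3)
    a1, b1 = information_criteria(-5.0, 2, 50)
    a2, b2 = information_criteria(-5.0, 3, 50)
    assert a2 > a1 and b2 > b1
    with pytest.raises(ValueError):
        information_criteria(0.0, 1, 0)


def test_corner_data_normalization_and_errors():
    rng = np.random.default_rng(0)
    chains = rng.standard_normal((400, 6, 3))
    data = corner_data(chains, burn_in=100, bins=20)
    assert len(data["marginals"]) == 3
    for edges, probs in data["marginals"]:
        assert probs.sum() == pytest.approx(1.0)
    assert set(data["pairs"]) == {(0, 1), (0, 2), (1, 2)}
    for _, _, H in data["pairs"].values():
        assert H.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        corner_data(chains, burn_in=400, bins=20)
    with pytest.raises(ValueError):
        corner_data(chains, burn_in=0, bins=1)
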