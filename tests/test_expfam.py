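"""Exponential-family calculus: maps, divergences, likelihood ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from omdetect import DomainError, MeanDomainError, get_family
from omdetect.expfam import BernoulliFamily, GammaFamily, GaussianFamily

from conftest import random_natural


@pytest.mark.parametrize(
    "name,d,theta,theta0,x,expected",
    [
        # identical parameters: ratio is exactly zero
        ("gaussian", 1, [0.0], [0.0], [1.3], 0.0),
        # hand evaluation, cross-checked against log(2 e^{-2x} / e^{-x}) at x=1
        ("gamma", 1, [-2.0], [-1.0], [1.0], -1.0 + np.log(2.0)),
        # direct density ratio p1/p0 = 0.8/0.2
        ("bernoulli", 1, [np.log(4.0)], [np.log(0.25)], [1.0], np.log(4.0)),
    ],
)
def test_log_likelihood_ratio_examples(name, d, theta, theta0, x, expected):
    fam = get_family(name, d)
    assert fam.log_likelihood_ratio(theta, theta0, x) == pytest.approx(expected, abs=1e-12)


def test_log_likelihood_ratio_antisymmetry(family, rng):
    t1 = random_natural(family, rng)
    t2 = random_natural(family, rng)
    x = family.sample(t1, 1, rng)[0]
    assert family.log_likelihood_ratio(t1, t2, x) == pytest.approx(
        -family.log_likelihood_ratio(t2, t1, x), abs=1e-12
    )


@pytest.mark.parametrize(
    "name,d,t1,t2,expected",
    [
        ("gaussian", 2, [1.0, 0.0], [0.0, 0.0], 0.5),       # ||t1-t2||^2/2
        ("gamma", 1, [-1.0], [-2.0], 1.0 - np.log(2.0)),    # KL(Exp(1)||Exp(2))
        ("bernoulli", 2, [0.3, -0.2], [0.3, -0.2], 0.0),    # equal parameters
    ],
)
def test_kl_examples(name, d, t1, t2, expected):
    fam = get_family(name, d)
    assert fam.kl(t1, t2) == pytest.approx(expected, abs=1e-12)


def test_kl_nonnegative_zero_iff_equal(family, rng):
    for _ in range(20):
        t1 = random_natural(family, rng)
        t2 = random_natural(family, rng)
        k = family.kl(t1, t2)
        assert k >= 0.0
        if not np.allclose(t1, t2):
            assert k > 0.0
    t = random_natural(family, rng)
    assert family.kl(t, t) == pytest.approx(0.0, abs=1e-12)


def test_mean_map_roundtrip(family, rng):
    for _ in range(100):
        theta = random_natural(family, rng)
        mu = family.mean_map(theta)
        back = family.inverse_mean_map(mu)
        assert np.abs(back - theta).max() <= 1e-9


@pytest.mark.parametrize(
    "name,arg,expected",
    [
        ("gaussian", [0.7], [0.7]),   # mean map is the identity
        ("bernoulli", [0.0], [0.5]),  # symmetry of the logistic map
    ],
)
def test_mean_map_examples(name, arg, expected):
    fam = get_family(name, 1)
    np.testing.assert_allclose(fam.mean_map(arg), expected)


def test_gamma_inverse_mean_map():
    fam = get_family("gamma")
    np.testing.assert_allclose(fam.inverse_mean_map([0.5]), [-2.0])


def test_fenchel_identity(family, rng):
    # Phi*(grad Phi(theta)) + Phi(theta) = theta' grad Phi(theta)
    for _ in range(100):
        theta = random_natural(family, rng)
        mu = family.mean_map(theta)
        lhs = family.dual(mu) + family.log_partition(theta)
        assert lhs == pytest.approx(float(theta @ mu), abs=1e-9)


def test_log_partition_convexity_1d(rng):
    # finite-difference second derivative of Phi is nonnegative
    h = 1e-4
    for fam, pts in [
        (get_family("gaussian", 1), rng.normal(size=8)),
        (get_family("gamma"), -np.exp(rng.normal(size=8))),
        (get_family("bernoulli", 1), rng.normal(size=8)),
    ]:
        for t in pts:
            f = lambda u: fam.log_partition([u])
            second = (f(t + h) - 2 * f(t) + f(t - h)) / h**2
            assert second >= -1e-6


def _kl_quadrature(fam, t1, t2):
    """Numerical-integration KL oracle for the 1-D families."""
    if isinstance(fam, GaussianFamily):
        pdf = lambda x: np.exp(-0.5 * (x - t1) ** 2) / np.sqrt(2 * np.pi)
        lo, hi = t1 - 12, t1 + 12
    elif isinstance(fam, GammaFamily):
        pdf = lambda x: -t1 * np.exp(t1 * x)
        lo, hi = 0.0, -40.0 / t1
    else:
        p1 = 1 / (1 + np.exp(-t1))
        p2 = 1 / (1 + np.exp(-t2))
        return p1 * np.log(p1 / p2) + (1 - p1) * np.log((1 - p1) / (1 - p2))
    integrand = lambda x: pdf(x) * fam.log_likelihood_ratio([t1], [t2], [x])
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


@pytest.mark.parametrize("name", ["gaussian", "gamma", "bernoulli"])
def test_kl_matches_quadrature_oracle(name, rng):
    fam = get_family(name, 1)
    for _ in range(10):
        t1 = float(random_natural(fam, rng)[0])
        t2 = float(random_natural(fam, rng)[0])
        assert fam.kl([t1], [t2]) == pytest.approx(_kl_quadrature(fam, t1, t2), abs=1e-5)


@pytest.mark.parametrize("name,d", [("gaussian", 2), ("gamma", 1), ("bernoulli", 3)])
def test_mean_log_ratio_converges_to_kl(name, d, rng):
    # law of large numbers: (1/n) sum log(f_theta/f_theta0)(X_i) -> KL(theta, theta0)
    fam = get_family(name, d)
    theta = random_natural(fam, rng, scale=0.5)
    theta0 = random_natural(fam, rng, scale=0.5)
    n = 10_000
    xs = fam.sample(theta, n, rng)
    vals = np.array([fam.log_likelihood_ratio(theta, theta0, x) for x in xs])
    se = vals.std(ddof=1) / np.sqrt(n)
    assert abs(vals.mean() - fam.kl(theta, theta0)) <= 3 * se + 1e-12


def test_domain_errors():
    gam = get_family("gamma")
    with pytest.raises(DomainError):
        gam.log_likelihood_ratio([1.0], [-1.0], [0.5])
    with pytest.raises(DomainError):
        gam.kl([0.0], [-1.0])
    bern = get_family("bernoulli", 1)
    with pytest.raises(MeanDomainError):
        bern.inverse_mean_map([0.0])
    with pytest.raises(MeanDomainError):
        bern.inverse_mean_map([1.0])
    with pytest.raises(MeanDomainError):
        gam.inverse_mean_map([-0.5])


def test_bernoulli_clamp_mean_adapts_with_sample_size():
    bern = get_family("bernoulli", 1)
    # n-sample guard uses the Krichevsky-Trofimov boundary 1/(2(n+1))
    assert bern.clamp_mean([0.0], n=1)[0] == pytest.approx(0.25)
    assert bern.clamp_mean([1.0], n=3)[0] == pytest.approx(1 - 1 / 8)
    assert bern.clamp_mean([0.5], n=1)[0] == pytest.approx(0.5)
    assert bern.clamp_mean([0.0])[0] == pytest.approx(1e-8)


@given(theta=st.floats(-20, 20), shift=st.floats(-5, 5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bernoulli_fenchel_identity_property(theta, shift):
    fam = get_family("bernoulli", 1)
    t = np.array([theta + shift])
    mu = fam.mean_map(t)
    if 0.0 < mu[0] < 1.0:
        assert fam.dual(mu) + fam.log_partition(t) == pytest.approx(float(t @ mu), abs=1e-8)


def test_bernoulli_product_structure(rng):
    # d-dimensional quantities are sums of the coordinate-wise ones
    d = 4
    fam = get_family("bernoulli", d)
    one = get_family("bernoulli", 1)
    t1, t2 = rng.normal(size=d), rng.normal(size=d)
    per_coord = sum(one.kl([a], [b]) for a, b in zip(t1, t2))
    assert fam.kl(t1, t2) == pytest.approx(per_coord, abs=1e-12)
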