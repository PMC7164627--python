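"""Density, sampler and latent-moment checks for the restricted skew-t."""

import numpy as np
import pytest
from scipy import integrate, stats

from skewtgmm import (
    MixtureClassParams,
    count_free_params,
    rmst_logdensity,
    sample_rmst,
)
from skewtgmm.growth import GrowthParams
from skewtgmm.mixture import _ClassKernel


def univariate_component(mu, sig2, delta, df):
    """A p=1 component (growth structure degenerate to a single occasion)."""
    g = GrowthParams(
        factor_means=[mu, 0.0],
        factor_cov=[[sig2 / 2, 0], [0, 0]],
        residual_vars=[sig2 / 2],
        time_scores=[0.0],
    )
    return MixtureClassParams(1.0, g, [delta], df)


@pytest.mark.parametrize(
    "skew_structure,class_varying,family,k,expected",
    [
        ("observed", "all", "normal", 1, 10),
        ("observed", "all", "normal", 2, 21),
        ("observed", "all", "skew_t", 1, 16),
        ("observed", "all", "t", 2, 23),
        ("observed", "means", "normal", 2, 13),
        ("observed", "means", "skew_t", 2, 19),
        ("factors", "all", "skew_t", 1, 13),
        ("factors", "means", "skew_t", 2, 16),
    ],
)
def test_free_parameter_count(skew_structure, class_varying, family, k, expected):
    assert count_free_params(family, k, 5, skew_structure, class_varying) == expected


def test_density_reduces_to_normal():
    """delta = 0, df = inf gives exactly the multivariate normal density."""
    g = GrowthParams([1.0, 0.5], [[1, 0.1], [0.1, 0.3]], [1, 1.5, 2], [0, 1, 2])
    cls = MixtureClassParams(1.0, g, np.zeros(3), np.inf)
    from skewtgmm.growth import implied_moments

    mom = implied_moments(g)
    rng = np.random.default_rng(0)
    ys = rng.normal(size=(20, 3)) * 2
    ours = rmst_logdensity(ys, cls)
    ref = stats.multivariate_normal(mom.mean, mom.cov).logpdf(ys)
    assert ours == pytest.approx(ref, rel=1e-10)


def test_standard_normal_at_mode():
    cls = univariate_component(0, 1, 0, np.inf)
    assert rmst_logdensity(np.array([0.0]), cls) == pytest.approx(
        np.log(0.3989422804014327)
    )


@pytest.mark.parametrize(
    "mu,sig2,delta,df",
    [(0, 1, 2, 5), (1, 2, -1.5, 3.5), (0.5, 1.3, 2.0, np.inf), (0, 1, 0, 4)],
    ids=["skew-t", "neg-skew-t", "skew-normal", "t"],
)
def test_univariate_density_integrates_to_one(mu, sig2, delta, df):
    cls = univariate_component(mu, sig2, delta, df)

    def f(x):
        return np.exp(rmst_logdensity(np.array([x]), cls))

    val, _ = integrate.quad(f, -80, 200, limit=400)
    assert val == pytest.approx(1.0, abs=1e-4)


def test_bivariate_density_integrates_to_one():
    g = GrowthParams([0.5, 0.3], [[0.6, 0.1], [0.1, 0.2]], [0.5, 0.7], [0, 1])
    cls = MixtureClassParams(1.0, g, [1.2, 0.8], 6.0)

    def f(y2, y1):
        return np.exp(rmst_logdensity(np.array([y1, y2]), cls))

    val, _ = integrate.dblquad(f, -20, 30, -20, 30, epsabs=1e-6)
    assert val == pytest.approx(1.0, abs=1e-4)


def _latent_moments_numeric(y0, mu, sig2, delta, df):
    """Brute-force posterior moments of (W, W U0, W U0^2) by dense 2-D
    Gauss-Legendre integration over the stochastic-representation hierarchy
    (independent of the closed forms under test)."""
    sig = np.sqrt(sig2)
    xu, wu = np.polynomial.legendre.leggauss(240)
    u0 = 0.5 * (xu + 1) * 12.0  # u0 in (0, 12)
    wu = wu * 6.0
    xw, ww = np.polynomial.legendre.leggauss(240)
    w = 0.5 * (xw + 1) * 30.0 + 1e-8  # w in (0, 30)
    ww = ww * 15.0
    U, W = np.meshgrid(u0, w)
    joint = (
        stats.gamma.pdf(W, df / 2, scale=2 / df)
        * 2 * stats.norm.pdf(U, 0, 1 / np.sqrt(W))
        * stats.norm.pdf(y0, mu + delta * U, sig / np.sqrt(W))
    )
    weight = np.outer(ww, wu)

    def e(fun):
        return float(np.sum(weight * joint * fun(U, W)))

    den = e(lambda u, w: 1.0)
    return (
        e(lambda u, w: w) / den,
        e(lambda u, w: w * u) / den,
        e(lambda u, w: w * u**2) / den,
    )


@pytest.mark.parametrize(
    "y0,mu,sig2,delta,df",
    [(1.2, 0, 1, 2, 5), (-0.7, 0.3, 1.5, -1.0, 8)],
    ids=["right-skew", "left-skew"],
)
def test_estep_moments_match_numerical_integration(y0, mu, sig2, delta, df):
    """The closed-form conditional expectations driving the EM E-step agree
    with direct numerical integration of the latent hierarchy."""
    cls = univariate_component(mu, sig2, delta, df)
    kern = _ClassKernel(cls)
    kern.prepare(np.array([[y0]]))
    e1, e2, e3 = kern.latent_moments()
    n1, n2, n3 = _latent_moments_numeric(y0, mu, sig2, delta, df)
    assert e1[0] == pytest.approx(n1, rel=1e-5)
    assert e2[0] == pytest.approx(n2, rel=1e-5)
    assert e3[0] == pytest.approx(n3, rel=1e-5)


def test_sampler_deterministic_and_nested():
    cls = univariate_component(0.3, 1.2, 0.0, np.inf)
    a = sample_rmst(cls, 500, seed=4)
    b = sample_rmst(cls, 500, seed=4)
    assert np.array_equal(a, b)
    # delta = 0, df = inf: plain normal draws
    big = sample_rmst(cls, 200_000, seed=5).ravel()
    assert big.mean() == pytest.approx(0.3, abs=3 * np.sqrt(1.2 / big.size))
    assert big.var() == pytest.approx(1.2, rel=0.02)


def test_sampler_halfnormal_mean_identity():
    """df = inf: E[Y] = mu + delta * sqrt(2/pi)."""
    delta = 2.0
    cls = univariate_component(0.0, 1.0, delta, np.inf)
    x = sample_rmst(cls, 400_000, seed=6).ravel()
    expect = delta * np.sqrt(2 / np.pi)
    assert x.mean() == pytest.approx(expect, abs=0.01)


def test_sampler_half_t_mean_identity():
    """Finite df: E|U0| = sqrt(df/pi) Gamma((df-1)/2) / Gamma(df/2)."""
    from scipy.special import gammaln

    df, delta = 5.0, 2.0
    cls = univariate_component(0.0, 1.0, delta, df)
    x = sample_rmst(cls, 400_000, seed=7).ravel()
    eu0 = np.sqrt(df / np.pi) * np.exp(gammaln((df - 1) / 2) - gammaln(df / 2))
    assert x.mean() == pytest.approx(delta * eu0, abs=0.02)


def test_density_matches_sampler_histogram():
    """Monte Carlo draws from the stochastic representation follow the
    closed-form density (coarse-bin histogram comparison)."""
    cls = univariate_component(0.0, 1.0, 2.0, 5.0)
    x = sample_rmst(cls, 500_000, seed=8).ravel()
    hist, edges = np.histogram(x, bins=50, range=(-4, 8), density=True)
    mids = 0.5 * (edges[1:] + edges[:-1])
    dens = np.exp([rmst_logdensity(np.array([m]), cls) for m in mids])
    binw = edges[1] - edges[0]
    se = np.sqrt(dens / (x.size * binw)) + 1e-4
    assert np.all(np.abs(hist - dens) < 4 * se + 0.003)
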