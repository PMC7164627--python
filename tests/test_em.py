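"""EM estimation: monotonicity, recovery, nesting, and a direct-maximization oracle."""

import numpy as np
import pytest
from scipy import optimize, stats

from skewtgmm import (
    StartPolicy,
    fit_em,
    generate_dataset,
    implied_moments,
    sample_rmst,
)
from skewtgmm.growth import GrowthParams
from skewtgmm.mixture import FAMILIES, MixtureClassParams
from skewtgmm.nonnormal import NonnormalSpec


def _random_instance(rng):
    """A random small dataset and fit configuration."""
    p = int(rng.integers(3, 6))
    growth = GrowthParams(
        factor_means=rng.normal(0, 1, 2),
        factor_cov=np.array([[1.0, 0.2], [0.2, 0.5]]) * rng.uniform(0.5, 2),
        residual_vars=rng.uniform(0.5, 3, p),
        time_scores=np.arange(p, dtype=float),
    )
    n = int(rng.integers(60, 120))
    spec = NonnormalSpec(*rng.choice([(0.0, 0.0), (1.0, 2.0)]))
    data = generate_dataset(growth, spec, n, seed=int(rng.integers(1 << 30)))
    family = str(rng.choice(FAMILIES))
    k = int(rng.choice([1, 2]))
    return data, family, k


@pytest.mark.parametrize("trial", range(20))
def test_em_loglik_monotone_and_posteriors_normalized(trial):
    """Across random instances the loglik trajectory never decreases and the
    posterior class probabilities are a proper soft assignment."""
    rng = np.random.default_rng(3000 + trial)
    data, family, k = _random_instance(rng)
    fit = fit_em(
        data, family, k,
        starts=StartPolicy(n_random=3, n_final=1, initial_iters=8),
        seed=trial, max_iter=80,
    )
    traj = fit.trajectory
    assert len(traj) >= 1
    diffs = np.diff(traj)
    assert np.all(diffs > -1e-8 * np.abs(traj[:-1]))
    assert fit.posteriors.shape == (len(data), k)
    assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-8)
    assert fit.n_params > 0


def test_one_class_normal_recovery(growth):
    """Fitting the generating family to a large sample recovers the growth
    parameters within sampling error."""
    n = 3200
    data = generate_dataset(growth, NonnormalSpec(0, 0), n, seed=42)
    fit = fit_em(data, "normal", 1, StartPolicy(n_random=5, n_final=2, base=growth), seed=1)
    assert fit.converged
    g = fit.model.classes[0].growth
    mom = implied_moments(growth)
    lam = growth.loadings
    # GLS sampling covariance of the factor-mean estimates
    alpha_cov = np.linalg.inv(lam.T @ np.linalg.inv(mom.cov) @ lam) / n
    se = np.sqrt(np.diag(alpha_cov))
    assert np.all(np.abs(g.factor_means - [1.0, 0.8]) < 3 * se)
    assert g.factor_cov[1, 1] == pytest.approx(0.20, abs=0.05)
    assert np.all(np.abs(g.residual_vars - growth.residual_vars) < 0.4)


def test_nesting_ladder(growth, quick_starts):
    """normal <= skew_normal <= skew_t and normal <= t <= skew_t in loglik."""
    data = generate_dataset(growth, NonnormalSpec(1, 2), 150, seed=5)
    ll = {
        fam: fit_em(data, fam, 1, quick_starts, seed=2).loglik
        for fam in FAMILIES
    }
    tol = 1e-4
    assert ll["normal"] <= ll["skew_normal"] + tol
    assert ll["skew_normal"] <= ll["skew_t"] + tol
    assert ll["normal"] <= ll["t"] + tol
    assert ll["t"] <= ll["skew_t"] + tol


def test_skew_t_on_normal_data_nests_normal(growth, quick_starts):
    data = generate_dataset(growth, NonnormalSpec(0, 0), 400, seed=9)
    ll_n = fit_em(data, "normal", 1, quick_starts, seed=3).loglik
    fit_st = fit_em(data, "skew_t", 1, quick_starts, seed=3)
    assert fit_st.loglik >= ll_n - 1e-4
    # on truly normal data the fitted skew stays small
    assert np.all(np.abs(fit_st.model.classes[0].skew) < 1.0)


def test_fit_deterministic_given_seed(growth, quick_starts):
    data = generate_dataset(growth, NonnormalSpec(0, 0), 120, seed=11)
    a = fit_em(data, "skew_normal", 1, quick_starts, seed=5)
    b = fit_em(data, "skew_normal", 1, quick_starts, seed=5)
    assert a.loglik == b.loglik
    assert a.iterations == b.iterations


# ---------------------------------------------------------------------------
# direct-maximization oracle on a tiny exactly-identified instance
# ---------------------------------------------------------------------------

P3 = np.arange(3, dtype=float)


def _build_growth(theta_vec):
    a0, a1, lsd0, lsd1, zrho, lt0, lt1, lt2 = theta_vec[:8]
    sd = np.exp([lsd0, lsd1])
    rho = np.tanh(zrho)
    psi = np.array(
        [[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]]
    )
    return GrowthParams([a0, a1], psi, np.exp([lt0, lt1, lt2]), P3)


def _direct_max(y, family):
    """Maximize the observed log-likelihood over free parameters directly
    (quasi-Newton on transformed coordinates), independent of the EM path."""
    from skewtgmm.mixture import rmst_logdensity

    n_extra = 3 if family == "skew_normal" else 0

    def neg_ll(vec):
        growth = _build_growth(vec)
        skew = vec[8 : 8 + n_extra] if n_extra else np.zeros(3)
        cls = MixtureClassParams(1.0, growth, skew, np.inf)
        try:
            return -float(np.sum(rmst_logdensity(y, cls)))
        except Exception:
            return 1e10

    x0 = np.array([0.5, 0.5, 0.0, -0.5, 0.1, 0.0, 0.0, 0.0] + [0.2] * n_extra)
    best = np.inf
    for shift in (0.0, 0.3):
        res = optimize.minimize(neg_ll, x0 + shift, method="Nelder-Mead",
                                options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(neg_ll, res.x, method="Nelder-Mead",
                                options={"maxiter": 8000, "xatol": 1e-9, "fatol": 1e-11})
        best = min(best, res.fun)
    return -best


@pytest.mark.parametrize("family", ["normal", "skew_normal"])
def test_em_matches_direct_maximization(family):
    """On a tiny exactly-identified instance (n = 40, three occasions) the EM
    optimum equals direct numerical maximization to 4 significant figures."""
    truth = GrowthParams([1.0, 0.5], [[0.8, 0.1], [0.1, 0.3]], [1.0, 1.2, 1.5], P3)
    cls = MixtureClassParams(1.0, truth, [0.8, 1.0, 1.2], np.inf)
    y = sample_rmst(cls, 40, seed=21)
    fit = fit_em(
        y, family, 1,
        StartPolicy(n_random=20, n_final=5, initial_iters=20, base=truth),
        seed=4, tol=1e-10, max_iter=5000,
    )
    ll_direct = _direct_max(y, family)
    assert fit.loglik == pytest.approx(ll_direct, rel=5e-5, abs=5e-3)
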