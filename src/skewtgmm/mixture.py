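"""Growth mixtures under the restricted multivariate skew-t (rMST) family.

Each mixture component follows the stochastic representation

    Y = mu + delta |U0| + U1,

where U0 is scalar, U1 is a p-vector, and (U0, U1) are jointly t-distributed
with a shared scale-mixing variable:  W ~ Gamma(nu/2, nu/2),
U0 | W ~ N(0, 1/W),  U1 | W ~ N_p(0, Sigma/W).  Marginalizing gives the
closed-form density

    f(y) = 2 t_p(y; mu, Omega, nu) T_1(M(y); nu + p),
    Omega = Sigma + delta delta',
    M(y)  = q(y) / sqrt(lam) * sqrt((nu + p) / (nu + d(y))),

with q(y) = delta' Omega^{-1} (y - mu), d(y) = (y - mu)' Omega^{-1} (y - mu)
and lam = 1 - delta' Omega^{-1} delta.  Setting delta = 0 recovers the
multivariate t, nu -> infinity the skew normal, and both the normal.

The location is structured by the linear growth model, mu = Lambda alpha,
and the scale by Sigma = Lambda Psi Lambda' + Theta, so the four families
form a strictly nested ladder of growth mixture models.  Estimation is by
EM treating (W, |U0|, eta) as missing data; the E-step needs only
univariate t tail probabilities, and degrees of freedom are updated by a
one-dimensional conditional maximization of the observed log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, special

from .growth import GrowthParams

logger = logging.getLogger(__name__)

FAMILIES = ("normal", "skew_normal", "t", "skew_t")

#: treat fitted df at/above this bound as the Gaussian limit
DF_MAX = 200.0
DF_MIN = 2.1

__all__ = [
    "FAMILIES",
    "MixtureClassParams",
    "MixtureModel",
    "FitResult",
    "StartPolicy",
    "family_has_skew",
    "family_has_df",
    "rmst_logdensity",
    "sample_rmst",
    "sample_mixture",
    "fit_em",
    "count_free_params",
]


def _t_logcdf(x: np.ndarray, df: float) -> np.ndarray:
    """log of the Student-t CDF via the fast stdtr ufunc.

    stdtr only underflows for astronomically deep tails; a floor keeps the
    log finite there (the exact value is irrelevant at that magnitude).
    """
    c = special.stdtr(df, x)
    return np.log(np.maximum(c, 1e-300))


def _row_logsumexp(a: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp of an (n, K) array (lean hot-path version)."""
    if a.shape[1] == 1:
        return a[:, 0]
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def family_has_skew(family: str) -> bool:
    return family in ("skew_normal", "skew_t")


def family_has_df(family: str) -> bool:
    return family in ("t", "skew_t")


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass
class MixtureClassParams:
    """Parameters of one mixture component.

    ``skew`` is a free p-vector on the observed occasions (zero for the
    symmetric families); ``df`` is the degrees of freedom (``inf`` for the
    Gaussian-limit families).  The location and scale are structured through
    ``growth``.
    """

    weight: float
    growth: GrowthParams
    skew: np.ndarray
    df: float = np.inf

    def __post_init__(self) -> None:
        self.skew = np.asarray(self.skew, dtype=float).ravel()

    def copy(self) -> "MixtureClassParams":
        return MixtureClassParams(
            weight=self.weight,
            growth=self.growth.copy(),
            skew=self.skew.copy(),
            df=self.df,
        )


@dataclass
class MixtureModel:
    """A K-component growth mixture of one rMST family.

    ``skew_structure`` records how the skew vector is parameterized:
    ``"observed"`` (default) leaves delta a free p-vector; ``"factors"``
    puts the skew on the growth factors, so the observed-occasion skew is
    delta_Y = Lambda delta_eta with 2 free parameters (level skew, slope
    skew).  ``class_varying`` controls parameter tying across classes:
    ``"all"`` (default) frees every parameter per class; ``"means"`` (the
    Mplus-default growth-mixture specification) lets only the factor means
    and weights differ by class, pooling Psi, Theta, skew and df.
    """

    family: str
    classes: list[MixtureClassParams]
    skew_structure: str = "observed"
    class_varying: str = "all"

    def __post_init__(self) -> None:
        _check_family(self.family)
        if self.skew_structure not in ("factors", "observed"):
            raise ValueError("skew_structure must be 'factors' or 'observed'")
        if self.class_varying not in ("means", "all"):
            raise ValueError("class_varying must be 'means' or 'all'")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes])

    def validate(self) -> None:
        if abs(sum(c.weight for c in self.classes) - 1.0) > 1e-8:
            raise ValueError("class weights must sum to 1")
        for c in self.classes:
            if not family_has_skew(self.family) and np.any(c.skew != 0):
                raise ValueError(f"family {self.family} requires zero skew")
            if not family_has_df(self.family) and np.isfinite(c.df):
                raise ValueError(f"family {self.family} requires df = inf")
            if family_has_df(self.family) and not c.df > 2:
                raise ValueError("finite df must exceed 2 (finite covariance)")

    def copy(self) -> "MixtureModel":
        return MixtureModel(
            self.family,
            [c.copy() for c in self.classes],
            self.skew_structure,
            self.class_varying,
        )


@dataclass
class FitResult:
    model: MixtureModel
    loglik: float
    n_params: int
    converged: bool
    iterations: int
    posteriors: np.ndarray
    trajectory: np.ndarray


def count_free_params(
    family: str,
    n_classes: int,
    p: int,
    skew_structure: str = "observed",
    class_varying: str = "all",
) -> int:
    """Free-parameter count of a K-class model with p occasions.

    Building blocks: 2 factor means, 3 factor (co)variances, p residual
    variances, the skew parameters (2 under the factor structure, p for a
    free observed-level vector), one df for the t families, and K - 1
    mixing weights.  Under ``class_varying="means"`` only the factor means
    repeat per class; under ``"all"`` every block does.
    """
    _check_family(family)
    extras = 0
    if family_has_skew(family):
        extras += 2 if skew_structure == "factors" else p
    if family_has_df(family):
        extras += 1
    if class_varying == "means":
        return 2 * n_classes + 3 + p + extras + (n_classes - 1)
    return n_classes * (2 + 3 + p + extras) + (n_classes - 1)


# ---------------------------------------------------------------------------
# per-class numerical kernel
# ---------------------------------------------------------------------------


class _DegenerateStart(Exception):
    """EM run hit a degenerate configuration (spiked class / singular scale)."""


class _ClassKernel:
    """Caches the linear-algebra work for one component at fixed parameters."""

    def __init__(self, cls: MixtureClassParams):
        g = cls.growth
        lam = g.loadings
        p = g.n_occasions
        self.p = p
        self.lam = lam
        self.alpha = g.factor_means
        self.psi = g.factor_cov
        self.theta = g.residual_vars
        self.delta = cls.skew
        self.df = cls.df
        self.mu = g.level1_intercepts + lam @ g.factor_means
        sigma = lam @ g.factor_cov @ lam.T + np.diag(g.residual_vars)
        self.sigma = sigma
        self.has_skew = bool(np.any(self.delta != 0))
        try:
            sigma_chol = np.linalg.cholesky(sigma)
            if self.has_skew:
                omega = sigma + np.outer(self.delta, self.delta)
                self.omega_chol = np.linalg.cholesky(omega)
            else:
                omega = sigma
                self.omega_chol = sigma_chol
        except np.linalg.LinAlgError as exc:
            raise _DegenerateStart("singular component scale matrix") from exc
        self.logdet_omega = 2.0 * np.sum(np.log(np.diag(self.omega_chol)))
        sigma_inv = sla.cho_solve(
            (sigma_chol, True), np.eye(p), check_finite=False
        )
        # Omega^{-1} delta and lam_qf = 1 - delta' Omega^{-1} delta
        if self.has_skew:
            self.omega_inv = sla.cho_solve(
                (self.omega_chol, True), np.eye(p), check_finite=False
            )
            oid = self.omega_inv @ self.delta
            self.lam_qf = float(max(1.0 - self.delta @ oid, 1e-12))
        else:
            self.omega_inv = sigma_inv
            oid = np.zeros(p)
            self.lam_qf = 1.0
        self.omega_inv_delta = oid
        # factor-posterior operators (use Sigma, the no-skew scale)
        self.A = self.psi @ lam.T @ sigma_inv  # (2, p)
        self.C = self.psi - self.A @ lam @ self.psi  # (2, 2)
        self.g_vec = self.A @ self.delta  # (2,)
        self._sigma_chol = sigma_chol
        # filled by prepare()
        self.u: np.ndarray | None = None
        self.d: np.ndarray | None = None
        self.q: np.ndarray | None = None

    def prepare(self, y: np.ndarray) -> None:
        """Cache centered data and the Omega quadratic forms for ``y``."""
        u = y - self.mu
        self.d = np.einsum("ij,ij->i", u @ self.omega_inv, u)
        self.q = u @ self.omega_inv_delta if self.has_skew else np.zeros(len(u))
        self.u = u
        self._logT1: np.ndarray | None = None  # cached skew-t CDF term

    # -- density --------------------------------------------------------

    def logpdf(self, df: float | None = None) -> np.ndarray:
        """rMST log-density at the prepared data (optionally overriding df)."""
        nu = self.df if df is None else df
        p, d, q = self.p, self.d, self.q
        has_skew = self.has_skew
        if np.isinf(nu):
            core = -0.5 * (p * np.log(2 * np.pi) + self.logdet_omega + d)
            if not has_skew:
                return core
            return np.log(2.0) + core + special.log_ndtr(q / np.sqrt(self.lam_qf))
        core = (
            special.gammaln((nu + p) / 2)
            - special.gammaln(nu / 2)
            - (p / 2) * np.log(nu * np.pi)
            - 0.5 * self.logdet_omega
            - ((nu + p) / 2) * np.log1p(d / nu)
        )
        if not has_skew:
            return core
        m = q / np.sqrt(self.lam_qf) * np.sqrt((nu + p) / (nu + d))
        logT1 = _t_logcdf(m, nu + p)
        if df is None:
            self._logT1 = logT1
        return np.log(2.0) + core + logT1

    # -- E-step latent moments -------------------------------------------

    def latent_moments(
        self, need_skew: bool | None = None
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        """Conditional expectations e1 = E[W|y], e2 = E[W U0|y], e3 = E[W U0^2|y].

        Closed forms use only univariate t tail probabilities; the skewing
        variable's posterior is a truncated normal given (W, y), and W's
        posterior is a gamma density tilted by a normal CDF.  ``need_skew``
        forces computation of (e2, e3) even at delta = 0 (where they are
        still well defined and move delta off zero in the next M-step).
        """
        nu, p, d, q = self.df, self.p, self.d, self.q
        lam_qf = self.lam_qf
        has_skew = self.has_skew if need_skew is None else need_skew
        if np.isinf(nu):
            e1 = np.ones_like(d)
            if not has_skew:
                return e1, None, None
            s = np.sqrt(lam_qf)
            zq = q / s
            log_phi = -0.5 * (zq**2 + np.log(2 * np.pi))
            h = np.exp(log_phi - special.log_ndtr(zq))
            e2 = q + s * h
            e3 = lam_qf + q * e2
            return e1, e2, e3
        if not has_skew:
            e1 = (nu + p) / (nu + d)
            return e1, None, None
        root = np.sqrt(1.0 / (nu + d))
        m2 = q / np.sqrt(lam_qf) * np.sqrt(nu + p + 2) * root
        if self._logT1 is not None:
            logT1 = self._logT1
        else:
            m1 = q / np.sqrt(lam_qf) * np.sqrt(nu + p) * root
            logT1 = _t_logcdf(m1, nu + p)
        logT2 = _t_logcdf(m2, nu + p + 2)
        e1 = (nu + p) / (nu + d) * np.exp(logT2 - logT1)
        d_sigma = d + q**2 / lam_qf
        a_half = (nu + p) / 2
        log_num = (
            special.gammaln(a_half + 0.5)
            - special.gammaln(a_half)
            + a_half * np.log((nu + d) / 2)
            - (a_half + 0.5) * np.log((nu + d_sigma) / 2)
            - 0.5 * np.log(2 * np.pi)
        )
        e2 = q * e1 + np.sqrt(lam_qf) * np.exp(log_num - logT1)
        e3 = lam_qf + q * e2
        return e1, e2, e3


# ---------------------------------------------------------------------------
# public density / sampler
# ---------------------------------------------------------------------------


def rmst_logdensity(y: np.ndarray, cls: MixtureClassParams) -> np.ndarray | float:
    """Log-density of the restricted multivariate skew-t component at ``y``.

    ``y`` may be a single p-vector or an (n, p) array; returns a scalar or an
    (n,) array accordingly.
    """
    arr = np.atleast_2d(np.asarray(y, dtype=float))
    kern = _ClassKernel(cls)
    kern.prepare(arr)
    out = kern.logpdf()
    return float(out[0]) if np.asarray(y).ndim == 1 else out


def sample_rmst(cls: MixtureClassParams, n: int, seed: int) -> np.ndarray:
    """Draw n rows from the component via the stochastic representation.

    A shared Gamma(nu/2, nu/2) mixing variable scales both the half-normal
    skewing draw and the Gaussian part, so (U0, U1) have the required joint
    t distribution.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    kern = _ClassKernel(cls)
    p = kern.p
    if np.isinf(cls.df):
        w = np.ones(n)
    else:
        w = rng.gamma(shape=cls.df / 2.0, scale=2.0 / cls.df, size=n)
    u0 = np.abs(rng.standard_normal(n)) / np.sqrt(w)
    eps = rng.standard_normal((n, p)) @ kern._sigma_chol.T / np.sqrt(w)[:, None]
    return kern.mu + np.outer(u0, cls.skew) + eps


def sample_mixture(model: MixtureModel, n: int, seed: int) -> pd.DataFrame:
    """Draw n subjects from a fitted mixture (class label then component draw)."""
    rng = np.random.default_rng(seed)
    weights = model.weights
    labels = rng.choice(model.n_classes, size=n, p=weights / weights.sum())
    p = model.classes[0].growth.n_occasions
    out = np.empty((n, p))
    child_seeds = rng.integers(0, 2**31 - 1, size=model.n_classes)
    for g, cls in enumerate(model.classes):
        idx = np.where(labels == g)[0]
        if idx.size:
            out[idx] = sample_rmst(cls, idx.size, int(child_seeds[g]))
    return pd.DataFrame(out, columns=[f"t{j + 1}" for j in range(p)])


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _estep_matrix(y: np.ndarray, model: MixtureModel) -> tuple[float, np.ndarray, list[_ClassKernel]]:
    n = y.shape[0]
    K = model.n_classes
    logl = np.empty((n, K))
    kernels = []
    for g, cls in enumerate(model.classes):
        kern = _ClassKernel(cls)
        kern.prepare(y)
        logl[:, g] = np.log(cls.weight) + kern.logpdf()
        kernels.append(kern)
    if K == 1:
        return float(logl.sum()), np.ones_like(logl), kernels
    row_lse = _row_logsumexp(logl)
    ll = float(np.sum(row_lse))
    z = np.exp(logl - row_lse[:, None])
    return ll, z, kernels


def _class_stats(
    y: np.ndarray, z: np.ndarray, kern: _ClassKernel, need_skew: bool
) -> dict:
    """Per-component expected sufficient statistics for the structured M-step.

    Treats the growth factors eta, the skewing variable U0 and the mixing
    variable W as missing data; everything reduces to (e1, e2, e3) and linear
    maps of them.  The pieces are additive across components, which lets the
    caller assemble either class-specific or class-invariant updates.
    """
    Z = float(z.sum())
    if Z <= 0:
        raise _DegenerateStart("empty component")
    m0 = kern.alpha + kern.u @ kern.A.T  # (n, 2) factor posterior means at u0=0
    lam = kern.lam
    if not need_skew and np.isinf(kern.df):
        # Gaussian component: W = 1, no skewing variable
        zm0 = z[:, None] * m0
        a = zm0.sum(axis=0)
        H = kern.C * Z + zm0.T @ m0
        return {
            "Z": Z, "Z1": Z, "a": a, "H": H,
            "t1": z @ (y**2),
            "t2": np.einsum("pa,pa->p", (z[:, None] * y).T @ m0, lam),
        }
    e1, e2, e3 = kern.latent_moments(need_skew=need_skew)
    ze1 = z * e1
    Z1 = float(ze1.sum())
    if Z1 <= 0:
        raise _DegenerateStart("empty component")
    g_vec = kern.g_vec
    if need_skew:
        ze2 = z * e2
        S3 = float((z * e3).sum())
        E_weta = e1[:, None] * m0 - np.outer(e2, g_vec)
    else:
        ze2 = None
        S3 = 0.0
        E_weta = e1[:, None] * m0
    a = z @ E_weta  # Sum_i z E[w eta]
    H = kern.C * Z + (ze1[:, None] * m0).T @ m0  # Sum_i z E[w eta eta']
    if need_skew:
        s2m0 = ze2 @ m0
        H -= np.outer(s2m0, g_vec) + np.outer(g_vec, s2m0)
        H += S3 * np.outer(g_vec, g_vec)
    lam = kern.lam
    out = {
        "Z": Z,
        "Z1": Z1,
        "a": a,
        "H": H,
        "t1": ze1 @ (y**2),
        "t2": np.einsum("pa,pa->p", (z[:, None] * y).T @ E_weta, lam),
    }
    if need_skew:
        v = ze2 @ m0 - S3 * g_vec  # Sum_i z E[w eta u0]
        ze2y = ze2 @ y
        out.update(v=v, ze2y=ze2y, v_num=ze2y - lam @ v, S3=S3)
    return out


def _solve_delta(
    v_num: np.ndarray, S3: float, lam: np.ndarray, theta_old: np.ndarray, structure: str
) -> np.ndarray:
    """Skew-vector update: unconstrained, or GLS-projected onto the loading
    space for the factor-structured parameterization (ECM with the previous
    Theta as weight)."""
    if structure == "factors":
        lam_w = lam / theta_old[:, None]  # Theta^{-1} Lambda
        d_eta = np.linalg.solve(lam.T @ lam_w, lam_w.T @ v_num)
        return lam @ d_eta / S3
    return v_num / S3


def _psi_fix(psi: np.ndarray) -> np.ndarray:
    psi = 0.5 * (psi + psi.T)
    # cheap 2x2 PSD check; eigen-clip only when violated
    det = psi[0, 0] * psi[1, 1] - psi[0, 1] * psi[1, 0]
    if psi[0, 0] > 0 and psi[1, 1] > 0 and det > 1e-12:
        return psi
    evals, evecs = np.linalg.eigh(psi)
    evals = np.maximum(evals, 1e-10)
    return (evecs * evals) @ evecs.T


def _theta_terms(st: dict, delta: np.ndarray, lam: np.ndarray, need_skew: bool) -> np.ndarray:
    """Numerator of the residual-variance update for one component at skew
    vector ``delta`` (diagonal of Sum_i z E[w eps eps'])."""
    num = st["t1"] - 2.0 * st["t2"] + np.einsum("pa,ab,pb->p", lam, st["H"], lam)
    if need_skew:
        num += -2.0 * delta * st["ze2y"] + 2.0 * delta * (lam @ st["v"]) + st["S3"] * delta**2
    return num


def _mstep(
    y: np.ndarray,
    z: np.ndarray,
    kernels: list[_ClassKernel],
    model: MixtureModel,
    theta_floor: np.ndarray,
) -> MixtureModel:
    """Structured M-step; honors the model's parameter-tying mode.

    ``class_varying == "all"`` (default): every parameter is class-specific.
    ``class_varying == "means"``: factor means and weights are
    class-specific while Psi, Theta, the skew vector and df are pooled.
    """
    family = model.family
    need_skew = family_has_skew(family)
    tied = model.class_varying == "means" and model.n_classes > 1
    n = y.shape[0]
    lam = kernels[0].lam
    stats = [
        _class_stats(y, z[:, g], kern, need_skew) for g, kern in enumerate(kernels)
    ]
    alphas = [st["a"] / st["Z1"] for st in stats]

    def psi_num(st: dict, alpha: np.ndarray) -> np.ndarray:
        return (
            st["H"]
            - np.outer(st["a"], alpha)
            - np.outer(alpha, st["a"])
            + st["Z1"] * np.outer(alpha, alpha)
        )

    new_classes = []
    if tied:
        if need_skew:
            S3 = sum(st["S3"] for st in stats)
            v_num = sum(st["v_num"] for st in stats)
            delta = _solve_delta(
                v_num, S3, lam, kernels[0].theta, model.skew_structure
            )
        else:
            delta = np.zeros(y.shape[1])
        psi = _psi_fix(sum(psi_num(st, al) for st, al in zip(stats, alphas)) / n)
        theta = sum(_theta_terms(st, delta, lam, need_skew) for st in stats) / n
        theta = np.maximum(theta, theta_floor)
        for st, alpha, kern in zip(stats, alphas, kernels):
            growth = GrowthParams(alpha, psi, theta, lam[:, 1])
            new_classes.append(
                MixtureClassParams(st["Z"] / n, growth, delta, kern.df)
            )
    else:
        for st, alpha, kern in zip(stats, alphas, kernels):
            if need_skew:
                delta = _solve_delta(
                    st["v_num"], st["S3"], lam, kern.theta, model.skew_structure
                )
            else:
                delta = np.zeros(y.shape[1])
            psi = _psi_fix(psi_num(st, alpha) / st["Z"])
            theta = _theta_terms(st, delta, lam, need_skew) / st["Z"]
            theta = np.maximum(theta, theta_floor)
            growth = GrowthParams(alpha, psi, theta, lam[:, 1])
            new_classes.append(
                MixtureClassParams(st["Z"] / n, growth, delta, kern.df)
            )
    return MixtureModel(family, new_classes, model.skew_structure, model.class_varying)


def _profile_df(neg_ll, current_df: float) -> float | None:
    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(np.log(DF_MIN), np.log(DF_MAX)),
        method="bounded",
        options={"xatol": 1e-2},
    )
    if -res.fun > -neg_ll(np.log(current_df)):
        return float(np.exp(res.x))
    return None


def _update_df(y: np.ndarray, model: MixtureModel) -> MixtureModel:
    """ECME step: 1-D maximization of the observed log-likelihood over df
    (bounded in [DF_MIN, DF_MAX]); a single shared df when the model ties
    parameters across classes.  Never decreases the log-likelihood."""
    n = y.shape[0]
    K = model.n_classes
    logl = np.empty((n, K))
    kernels = []
    for g, cls in enumerate(model.classes):
        kern = _ClassKernel(cls)
        kern.prepare(y)
        logl[:, g] = np.log(cls.weight) + kern.logpdf()
        kernels.append(kern)
    log_w = np.log(model.weights)
    if model.class_varying == "means" and K > 1:

        def neg_ll_shared(log_nu: float) -> float:
            nu = float(np.exp(log_nu))
            cols = np.column_stack(
                [log_w[g] + kernels[g].logpdf(df=nu) for g in range(K)]
            )
            return -float(_row_logsumexp(cols).sum())

        nu_new = _profile_df(neg_ll_shared, model.classes[0].df)
        if nu_new is not None:
            for cls in model.classes:
                cls.df = nu_new
        return model
    for g, cls in enumerate(model.classes):
        kern = kernels[g]
        if K > 1:
            other_lse = _row_logsumexp(np.delete(logl, g, axis=1))

        def neg_ll(log_nu: float) -> float:
            col = log_w[g] + kern.logpdf(df=float(np.exp(log_nu)))
            if K == 1:
                return -float(col.sum())
            return -float(_row_logsumexp(np.column_stack([other_lse, col])).sum())

        nu_new = _profile_df(neg_ll, cls.df)
        if nu_new is not None:
            cls.df = nu_new
            logl[:, g] = log_w[g] + kern.logpdf(df=nu_new)
    return model


def _em_run(
    y: np.ndarray,
    model: MixtureModel,
    tol: float,
    max_iter: int,
    theta_floor: np.ndarray,
    weight_floor: float,
    df_update_every: int = 5,
) -> tuple[MixtureModel, float, bool, int, np.ndarray, list[float]]:
    family = model.family
    has_df = family_has_df(family)
    ll_prev = -np.inf
    trajectory: list[float] = []
    z = np.full((y.shape[0], model.n_classes), 1.0 / model.n_classes)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, z, kernels = _estep_matrix(y, model)
        trajectory.append(ll)
        if not np.isfinite(ll):
            raise _DegenerateStart("non-finite log-likelihood")
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-10):
            converged = True
            break
        ll_prev = ll
        model = _mstep(y, z, kernels, model, theta_floor)
        for g, cls_new in enumerate(model.classes):
            if cls_new.weight < weight_floor:
                raise _DegenerateStart(
                    f"component {g} weight {cls_new.weight:.4g} below floor"
                )
        if has_df and (it % df_update_every == 0):
            model = _update_df(y, model)
    if not converged:
        # cap hit after an M-step: refresh ll/posteriors for the final model
        ll, z, _ = _estep_matrix(y, model)
        trajectory.append(ll)
    return model, trajectory[-1], converged, it, z, trajectory


@dataclass
class StartPolicy:
    """Multi-start policy for EM.

    The base start (true/generating parameters when known, otherwise a
    moment-based start) plus ``n_random`` perturbed starts all run a short
    initial stage of ``initial_iters`` EM iterations; the best ``n_final``
    by log-likelihood continue to full convergence (two-stage multistart in
    the Mplus tradition).  The perturbation dispersion is deliberately wide
    (Mplus STSCALE-like): the spurious-class optima that drive
    over-extraction live far from moment-based starts, and narrow scatter
    demonstrably under-maximizes multi-class likelihoods.
    """

    n_random: int = 100
    n_final: int = 10
    initial_iters: int = 20
    perturb_loc: float = 2.5
    perturb_scale: float = 1.4
    base: GrowthParams | None = None


def _moment_start(y: np.ndarray) -> GrowthParams:
    """Moment-based starting growth parameters for arbitrary data."""
    p = y.shape[1]
    tscores = np.arange(p, dtype=float)
    lam = np.column_stack([np.ones(p), tscores])
    ybar = y.mean(axis=0)
    alpha, *_ = np.linalg.lstsq(lam, ybar, rcond=None)
    s = np.cov(y.T)
    pinv = np.linalg.pinv(lam)
    psi = pinv @ s @ pinv.T * 0.5
    psi = 0.5 * (psi + psi.T)
    evals, evecs = np.linalg.eigh(psi)
    psi = (evecs * np.maximum(evals, 0.05)) @ evecs.T
    theta = np.maximum(0.5 * np.diag(s), 0.05)
    return GrowthParams(alpha, psi, theta, tscores)


def _base_model(
    y: np.ndarray,
    family: str,
    n_classes: int,
    policy: StartPolicy,
    skew_structure: str = "observed",
    class_varying: str = "all",
) -> MixtureModel:
    base = policy.base.copy() if policy.base is not None else _moment_start(y)
    p = base.n_occasions
    df0 = 10.0 if family_has_df(family) else np.inf
    classes = []
    if n_classes == 1:
        classes.append(
            MixtureClassParams(1.0, base.copy(), np.zeros(p), df0)
        )
    else:
        # low/high mean pattern for the multi-class start
        patterns = [np.array([0.0, 0.0]), np.array([1.5, 1.6])]
        while len(patterns) < n_classes:
            patterns.append(base.factor_means + np.random.default_rng(len(patterns)).normal(0, 1, 2))
        for g in range(n_classes):
            gp = base.copy()
            gp.factor_means = patterns[g].copy()
            classes.append(
                MixtureClassParams(1.0 / n_classes, gp, np.zeros(p), df0)
            )
    return MixtureModel(family, classes, skew_structure, class_varying)


def _perturb_model(
    model: MixtureModel, rng: np.random.Generator, policy: StartPolicy, data_sd: np.ndarray
) -> MixtureModel:
    out = model.copy()
    K = out.n_classes
    weights = rng.dirichlet(np.full(K, 5.0)) if K > 1 else np.array([1.0])
    for g, cls in enumerate(out.classes):
        gw = cls.growth
        scale = np.sqrt(np.diag(gw.factor_cov)) + 0.3
        gw.factor_means = gw.factor_means + rng.normal(0, policy.perturb_loc, 2) * scale
        dpsi = np.sqrt(np.diag(gw.factor_cov))
        r = gw.factor_cov[0, 1] / (dpsi[0] * dpsi[1])
        r = float(np.clip(r + rng.normal(0, 0.15), -0.85, 0.85))
        dpsi = dpsi * np.exp(rng.normal(0, policy.perturb_scale, 2))
        gw.factor_cov = np.array(
            [[dpsi[0] ** 2, r * dpsi[0] * dpsi[1]], [r * dpsi[0] * dpsi[1], dpsi[1] ** 2]]
        )
        gw.residual_vars = gw.residual_vars * np.exp(
            rng.normal(0, policy.perturb_scale, gw.residual_vars.size)
        )
        if family_has_skew(out.family):
            if out.skew_structure == "factors":
                cls.skew = cls.skew + gw.loadings @ rng.normal(0, 0.4, 2)
            else:
                cls.skew = cls.skew + rng.normal(0, 0.3, cls.skew.size) * data_sd
        if family_has_df(out.family):
            cls.df = float(np.exp(rng.uniform(np.log(3.0), np.log(40.0))))
        cls.weight = float(weights[g])
    if out.class_varying == "means" and K > 1:
        # keep the tied blocks identical across classes in the start
        ref = out.classes[0]
        for cls in out.classes[1:]:
            cls.growth.factor_cov = ref.growth.factor_cov.copy()
            cls.growth.residual_vars = ref.growth.residual_vars.copy()
            cls.skew = ref.skew.copy()
            cls.df = ref.df
    return out


def fit_em(
    data,
    family: str,
    n_classes: int,
    starts: StartPolicy | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    skew_structure: str = "observed",
    class_varying: str = "all",
) -> FitResult:
    """Fit a K-class growth mixture by multi-start EM.

    Parameters
    ----------
    data : DataFrame or (n, p) array
        One row per subject, one column per occasion.
    family : {"normal", "skew_normal", "t", "skew_t"}
    n_classes : int
    starts : StartPolicy, optional
        Multi-start configuration; defaults mirror the 100-random-start
        two-stage convention.
    seed : int
        Seeds the random perturbations (fits are deterministic given it).
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        EM iteration cap per start.

    Returns the best solution over all starts; never raises on
    non-convergence (``converged`` flag instead).  Degenerate starts
    (spiked classes, singular scales) are discarded and logged.
    """
    _check_family(family)
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be 2-D (subjects x occasions)")
    n = y.shape[0]
    policy = starts if starts is not None else StartPolicy()
    q = count_free_params(family, n_classes, y.shape[1], skew_structure, class_varying)
    if n <= q:
        raise ValueError(f"need n > {q} free parameters, got n = {n}")
    rng = np.random.default_rng(seed)
    data_sd = y.std(axis=0)
    theta_floor = np.maximum(1e-6 * y.var(axis=0), 1e-10)
    weight_floor = 1.0 / n
    base = _base_model(y, family, n_classes, policy, skew_structure, class_varying)
    start_models = [base] + [
        _perturb_model(base, rng, policy, data_sd) for _ in range(policy.n_random)
    ]
    # stage 1: short runs
    stage1: list[tuple[float, MixtureModel, int]] = []
    for m in start_models:
        try:
            # short ranking runs: df profiling deferred to the final stage
            mod, ll, conv, it, _, _ = _em_run(
                y, m.copy(), tol, policy.initial_iters, theta_floor, weight_floor,
                df_update_every=10**9,
            )
        except _DegenerateStart as exc:
            logger.debug("discarded start: %s", exc)
            continue
        stage1.append((ll, mod, it))
    if not stage1:
        logger.warning("all EM starts degenerate; returning base start unfit")
        ll0, z0, _ = -np.inf, np.full((n, n_classes), 1.0 / n_classes), None
        return FitResult(base, ll0, q, False, 0, z0, np.array([]))
    stage1.sort(key=lambda t: -t[0])
    # stage 2: continue the best few to full convergence
    best: tuple[float, MixtureModel, bool, int, np.ndarray, list[float]] | None = None
    for ll1, mod, it1 in stage1[: max(policy.n_final, 1)]:
        try:
            mod2, ll2, conv, it2, z2, traj = _em_run(
                y, mod, tol, max_iter, theta_floor, weight_floor
            )
        except _DegenerateStart as exc:
            logger.debug("discarded stage-2 start: %s", exc)
            continue
        if best is None or ll2 > best[0]:
            best = (ll2, mod2, conv, it1 + it2, z2, traj)
    if best is None:
        logger.warning("all stage-2 starts degenerate; returning best stage-1 model")
        ll1, mod, it1 = stage1[0]
        _, z1, _ = _estep_matrix(y, mod)
        return FitResult(mod, ll1, q, False, it1, z1, np.array([ll1]))
    ll, mod, conv, iters, z, traj = best
    return FitResult(mod, ll, q, conv, iters, z, np.asarray(traj))
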