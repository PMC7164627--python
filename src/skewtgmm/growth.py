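"""Linear latent growth model: parameters and implied observation moments.

The unconditional linear growth model for p repeated measures is

    y_i = nu + Lambda eta_i + eps_i,      eta_i = alpha + xi_i,

with eta_i = (intercept_i, slope_i)', Lambda = [1 | t] for time scores t,
xi_i ~ N(0, Psi) and eps_i ~ N(0, Theta) with diagonal Theta.  The implied
marginal moments of y are

    E[y]   = nu + Lambda alpha,
    Cov[y] = Lambda Psi Lambda' + Theta.

Both the data generator and the structured mean/covariance parameterisation
used during mixture fitting are driven by these two formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "ImpliedMoments",
    "default_growth_params",
    "implied_moments",
]


class InvalidParameterError(ValueError):
    """Raised when growth parameters violate their invariants."""


@dataclass
class GrowthParams:
    """Parameters of a linear latent growth model.

    Attributes
    ----------
    factor_means : (2,) array
        Means of the intercept and slope factors, alpha = (mu_alpha, mu_beta).
    factor_cov : (2, 2) array
        Covariance matrix Psi of the growth factors (symmetric PSD).
    residual_vars : (p,) array
        Diagonal of the occasion-specific residual covariance Theta (all > 0).
    time_scores : (p,) array
        Time scores; the loading matrix is [ones | time_scores].
    level1_intercepts : (p,) array
        Per-occasion intercepts nu; zero in the standard unconditional
        identification (means carried by the factor means).
    """

    factor_means: np.ndarray
    factor_cov: np.ndarray
    residual_vars: np.ndarray
    time_scores: np.ndarray
    level1_intercepts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.factor_means = np.asarray(self.factor_means, dtype=float).reshape(2)
        self.factor_cov = np.asarray(self.factor_cov, dtype=float).reshape(2, 2)
        self.residual_vars = np.asarray(self.residual_vars, dtype=float).ravel()
        self.time_scores = np.asarray(self.time_scores, dtype=float).ravel()
        if self.level1_intercepts is None:
            self.level1_intercepts = np.zeros_like(self.residual_vars)
        else:
            self.level1_intercepts = np.asarray(
                self.level1_intercepts, dtype=float
            ).ravel()

    @property
    def n_occasions(self) -> int:
        return self.residual_vars.size

    @property
    def loadings(self) -> np.ndarray:
        """p x 2 loading matrix: column 1 all ones, column 2 the time scores."""
        return np.column_stack(
            [np.ones_like(self.time_scores), self.time_scores]
        )

    def validate(self) -> None:
        """Check the invariants; raise :class:`InvalidParameterError` if violated."""
        if self.time_scores.size != self.residual_vars.size:
            raise InvalidParameterError("time_scores and residual_vars length mismatch")
        if not np.allclose(self.factor_cov, self.factor_cov.T):
            raise InvalidParameterError("factor covariance is not symmetric")
        eigvals = np.linalg.eigvalsh(0.5 * (self.factor_cov + self.factor_cov.T))
        if eigvals.min() < -1e-10:
            raise InvalidParameterError("factor covariance is not positive semi-definite")
        if np.any(self.residual_vars <= 0):
            raise InvalidParameterError("residual variances must be strictly positive")

    def copy(self) -> "GrowthParams":
        return GrowthParams(
            factor_means=self.factor_means.copy(),
            factor_cov=self.factor_cov.copy(),
            residual_vars=self.residual_vars.copy(),
            time_scores=self.time_scores.copy(),
            level1_intercepts=self.level1_intercepts.copy(),
        )

    # -- flat key=value config serialization (matrices row-major) ------------

    def to_config(self) -> str:
        """Serialize to a flat ``key = v1 v2 ...`` text block (row-major)."""
        def fmt(arr: np.ndarray) -> str:
            return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())

        lines = [
            f"factor_means = {fmt(self.factor_means)}",
            f"factor_cov = {fmt(self.factor_cov)}",
            f"residual_vars = {fmt(self.residual_vars)}",
            f"time_scores = {fmt(self.time_scores)}",
            f"level1_intercepts = {fmt(self.level1_intercepts)}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "GrowthParams":
        fields: dict[str, np.ndarray] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = np.array([float(v) for v in value.split()])
        p = fields["residual_vars"].size
        return cls(
            factor_means=fields["factor_means"],
            factor_cov=fields["factor_cov"].reshape(2, 2),
            residual_vars=fields["residual_vars"],
            time_scores=fields["time_scores"],
            level1_intercepts=fields.get("level1_intercepts", np.zeros(p)),
        )


@dataclass
class ImpliedMoments:
    """Model-implied marginal mean vector and covariance matrix of y."""

    mean: np.ndarray
    cov: np.ndarray


def default_growth_params() -> GrowthParams:
    """Generating parameters of the single-class population studied here.

    A rising mean trajectory (mu_alpha = 1.00, mu_beta = 0.80) over five
    occasions with time scores 0..4, individual variability in both level and
    change (Psi_alpha = 1.00, Psi_beta = 0.20, Psi_alphabeta = 0.11), and
    residual variances that grow over time,
    Theta = diag(1.00, 1.42, 2.25, 3.47, 5.09).
    """
    return GrowthParams(
        factor_means=np.array([1.00, 0.80]),
        factor_cov=np.array([[1.00, 0.11], [0.11, 0.20]]),
        residual_vars=np.array([1.00, 1.42, 2.25, 3.47, 5.09]),
        time_scores=np.arange(5, dtype=float),
    )


def implied_moments(params: GrowthParams) -> ImpliedMoments:
    """Marginal mean and covariance of y implied by growth parameters.

    mean = nu + Lambda alpha;  cov = Lambda Psi Lambda' + Theta.
    """
    params.validate()
    lam = params.loadings
    mean = params.level1_intercepts + lam @ params.factor_means
    cov = lam @ params.factor_cov @ lam.T + np.diag(params.residual_vars)
    return ImpliedMoments(mean=mean, cov=cov)
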