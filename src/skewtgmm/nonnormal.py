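"""Nonnormal longitudinal data generation (Fleishman / Vale-Maurelli).

A standard normal deviate Z is pushed through the cubic polynomial

    X = a + b Z + c Z^2 + d Z^3,        a = -c,

with coefficients chosen so X has mean 0, variance 1 and prescribed
skewness and excess kurtosis (Fleishman power method).  The Vale-Maurelli
extension chooses "intermediate" correlations among the underlying normals
so that the transformed variables hit a target correlation matrix, which
lets us impose the growth model's implied covariance structure while making
each margin nonnormal.  The nonnormality is injected on the observed
margins (the transformed, standardized observations), mirroring the EQS
simulation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import GrowthParams, implied_moments

__all__ = [
    "NonnormalSpec",
    "FleishmanCoeffs",
    "solve_fleishman",
    "fleishman_moments",
    "intermediate_correlation",
    "generate_dataset",
]


class InfeasibleSpecError(ValueError):
    """Target skew/kurtosis outside the power method's feasible region."""


class IntermediateCorrelationError(ValueError):
    """No valid intermediate correlation (or non-PD intermediate matrix)."""


@dataclass(frozen=True)
class NonnormalSpec:
    """Target marginal skewness and excess kurtosis (same for all occasions)."""

    skew: float
    ex_kurtosis: float

    def is_feasible(self) -> bool:
        # Feasibility boundary of the cubic transform.
        return self.ex_kurtosis >= self.skew**2 - 2

    @property
    def is_normal(self) -> bool:
        return self.skew == 0.0 and self.ex_kurtosis == 0.0


@dataclass(frozen=True)
class FleishmanCoeffs:
    a: float
    b: float
    c: float
    d: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        return self.a + z * (self.b + z * (self.c + z * self.d))


def fleishman_moments(co: FleishmanCoeffs) -> tuple[float, float, float, float]:
    """Exact (mean, variance, skewness, excess kurtosis) of the cubic transform.

    Computed by Gauss-Hermite quadrature, which is exact here: central moments
    up to order four of a cubic polynomial in Z are polynomial integrands of
    degree <= 12 against the normal weight.  This is deliberately independent
    of the moment system used by the solver.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(12)
    w = weights / np.sqrt(2 * np.pi)
    x = co.transform(nodes)
    mean = float(w @ x)
    xc = x - mean
    var = float(w @ xc**2)
    skew = float(w @ xc**3) / var**1.5
    exkurt = float(w @ xc**4) / var**2 - 3.0
    return mean, var, skew, exkurt


def solve_fleishman(spec: NonnormalSpec, tol: float = 1e-11) -> FleishmanCoeffs:
    """Solve the Fleishman moment system for the target spec.

    Returns the root with b > 0 (the orientation-preserving transform).
    The normal spec (0, 0) returns the identity transform exactly.
    """
    if not spec.is_feasible():
        raise InfeasibleSpecError(
            f"spec skew={spec.skew}, ex_kurtosis={spec.ex_kurtosis} lies outside "
            "the feasible region (need ex_kurtosis >= skew^2 - 2)"
        )
    if spec.is_normal:
        return FleishmanCoeffs(0.0, 1.0, 0.0, 0.0)

    g1, g2 = spec.skew, spec.ex_kurtosis

    def system(x: np.ndarray) -> np.ndarray:
        b, c, d = x
        return np.array(
            [
                b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0,
                2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - g1,
                24
                * (
                    b * d
                    + c**2 * (1 + b**2 + 28 * b * d)
                    + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)
                )
                - g2,
            ]
        )

    sol = optimize.root(system, x0=np.array([1.0, 0.0, 0.0]), method="hybr", tol=1e-13)
    b, c, d = sol.x
    if not sol.success or np.max(np.abs(system(sol.x))) > tol or b <= 0:
        raise InfeasibleSpecError(
            f"Fleishman solver failed for skew={g1}, ex_kurtosis={g2}: {sol.message}"
        )
    return FleishmanCoeffs(a=-c, b=float(b), c=float(c), d=float(d))


def intermediate_correlation(
    target_r: float, ci: FleishmanCoeffs, cj: FleishmanCoeffs
) -> float:
    """Intermediate normal correlation rho_z reproducing ``target_r`` post-transform.

    Solves the Vale-Maurelli cubic

        rho (b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
        + 2 rho^2 c_i c_j + 6 rho^3 d_i d_j = target_r
    """
    if not abs(target_r) < 1:
        raise IntermediateCorrelationError(f"|target_r| must be < 1, got {target_r}")
    lin = ci.b * cj.b + 3 * ci.b * cj.d + 3 * ci.d * cj.b + 9 * ci.d * cj.d
    quad = 2 * ci.c * cj.c
    cub = 6 * ci.d * cj.d
    # highest-degree first for numpy
    roots = np.roots([cub, quad, lin, -target_r])
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = real[(real > -1.0) & (real < 1.0)]
    if inside.size == 0:
        raise IntermediateCorrelationError(
            f"no intermediate correlation in (-1, 1) for target {target_r}"
        )
    # the VM polynomial is monotone on the feasible region; if numerics yield
    # several candidates keep the one whose image is closest to the target
    def image(r: float) -> float:
        return r * lin + r * r * quad + r**3 * cub

    best = min(inside, key=lambda r: abs(image(r) - target_r))
    return float(best)


def _intermediate_matrix(target_corr: np.ndarray, co: FleishmanCoeffs) -> np.ndarray:
    p = target_corr.shape[0]
    rz = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            rz[i, j] = rz[j, i] = intermediate_correlation(
                float(target_corr[i, j]), co, co
            )
    return rz


def generate_dataset(
    params: GrowthParams,
    spec: NonnormalSpec,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Generate an n x p dataset with the growth model's implied moments.

    Pipeline: standardize implied moments -> Vale-Maurelli intermediate
    correlation matrix -> multivariate normal draw -> Fleishman transform per
    column -> rescale to the implied means and variances.  Deterministic
    given ``seed``.  A non-positive-definite intermediate matrix raises
    :class:`IntermediateCorrelationError` (an infeasible design is an error,
    not something to repair silently).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    mom = implied_moments(params)
    sd = np.sqrt(np.diag(mom.cov))
    target_corr = mom.cov / np.outer(sd, sd)
    co = solve_fleishman(spec)
    if spec.is_normal:
        rz = target_corr
    else:
        rz = _intermediate_matrix(target_corr, co)
    try:
        chol = np.linalg.cholesky(rz)
    except np.linalg.LinAlgError as exc:
        raise IntermediateCorrelationError(
            "intermediate correlation matrix is not positive definite; the "
            "requested skew/kurtosis cannot jointly realize the implied "
            "correlations (consider a nearest-PD repair upstream)"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(sd))) @ chol.T
    x = co.transform(z)
    y = mom.mean + sd * x
    cols = [f"t{j + 1}" for j in range(len(sd))]
    return pd.DataFrame(y, columns=cols)
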