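"""Class-enumeration criteria: information criteria and likelihood-ratio tests.

Given fits with k and k-1 latent classes, the tools here answer the applied
question "how many trajectory classes does this sample support?":

* penalized-likelihood indices AIC, BIC and the sample-size-adjusted BIC
  (SBIC), each preferring the candidate with the smallest value;
* the Vuong-Lo-Mendell-Rubin likelihood-ratio test and its adjusted
  variant, analytic tests of k-1 vs k classes;
* the parametric bootstrap likelihood-ratio test (BLRT), which simulates
  the null distribution of the LR statistic from the fitted (k-1)-class
  model.

The exact VLMR reference distribution is a data-dependent weighted sum of
chi-square variables whose weights require per-observation score and
information estimates.  We use the tractable approximation long recommended
for mixture likelihood-ratio tests: refer 2*dLL to a chi-square with TWICE
the difference in free parameters as degrees of freedom (the boundary
problem makes the naive chi-square far too light-tailed), with the
Bartlett-style factor c = 1 + 1/(dq ln n) deflating the statistic for the
adjusted variant.  Like the score-based original, the resulting test is
approximately calibrated but mildly anticonservative on single-class null
growth-mixture data; the bootstrap LRT is the calibrated alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mixture import (
    FitResult,
    StartPolicy,
    fit_em,
    sample_mixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnumerationResult",
    "information_criteria",
    "select_by_index",
    "vlmr_lrt",
    "lmr_adjusted_lrt",
    "blrt",
]

#: significance threshold used when an LRT "selects" the larger model
ALPHA = 0.05


@dataclass
class EnumerationResult:
    """Per-replication record of index values, test p-values and decisions."""

    aic: dict[int, float]
    bic: dict[int, float]
    sbic: dict[int, float]
    vlmr_p: float | None = None
    lmr_p: float | None = None
    blrt_p: float | None = None
    selected_by: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        rec = {
            "aic": {str(k): v for k, v in self.aic.items()},
            "bic": {str(k): v for k, v in self.bic.items()},
            "sbic": {str(k): v for k, v in self.sbic.items()},
            "vlmr_p": self.vlmr_p,
            "lmr_p": self.lmr_p,
            "blrt_p": self.blrt_p,
            "selected_by": self.selected_by,
        }
        return json.dumps(rec)

    @classmethod
    def from_json(cls, text: str) -> "EnumerationResult":
        rec = json.loads(text)
        return cls(
            aic={int(k): v for k, v in rec["aic"].items()},
            bic={int(k): v for k, v in rec["bic"].items()},
            sbic={int(k): v for k, v in rec["sbic"].items()},
            vlmr_p=rec.get("vlmr_p"),
            lmr_p=rec.get("lmr_p"),
            blrt_p=rec.get("blrt_p"),
            selected_by={k: int(v) for k, v in rec.get("selected_by", {}).items()},
        )


def information_criteria(fit: FitResult, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, SBIC) of a fit on a sample of size n.

    aic = -2 LL + 2q;  bic = -2 LL + q ln n;  sbic = -2 LL + q ln((n+2)/24).
    """
    if not np.isfinite(fit.loglik):
        raise ValueError("log-likelihood is not finite")
    q = fit.n_params
    m2ll = -2.0 * fit.loglik
    return (
        m2ll + 2.0 * q,
        m2ll + q * np.log(n),
        m2ll + q * np.log((n + 2) / 24.0),
    )


def select_by_index(candidates: list[tuple[int, float]]) -> int:
    """Class count with the smallest index value; ties favor fewer classes."""
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(candidates, key=lambda kv: (kv[1], kv[0]))[0]


class NonConvergedTestError(ValueError):
    """LRT requested on a non-converged fit."""


def _lrt_inputs(fit_k: FitResult, fit_km1: FitResult) -> tuple[float, int]:
    if not (fit_k.converged and fit_km1.converged):
        raise NonConvergedTestError("both fits must have converged")
    lr = 2.0 * (fit_k.loglik - fit_km1.loglik)
    df = fit_k.n_params - fit_km1.n_params
    if df <= 0:
        raise ValueError("fit_k must have more free parameters than fit_km1")
    return max(lr, 0.0), df


def vlmr_lrt(fit_k: FitResult, fit_km1: FitResult, n: int) -> float:
    """p-value of the Vuong-Lo-Mendell-Rubin test of k-1 vs k classes.

    Uses the chi-square approximation with 2 * (difference in free
    parameters) degrees of freedom (see module docstring).
    """
    lr, dq = _lrt_inputs(fit_k, fit_km1)
    return float(stats.chi2.sf(lr, 2 * dq))


def lmr_adjusted_lrt(fit_k: FitResult, fit_km1: FitResult, n: int) -> float:
    """p-value of the LMR-adjusted test (small-sample deflation of the VLMR
    statistic by c = 1 + 1/(dq ln n))."""
    lr, dq = _lrt_inputs(fit_k, fit_km1)
    c = 1.0 + 1.0 / (dq * np.log(n))
    return float(stats.chi2.sf(lr / c, 2 * dq))


def blrt(
    data,
    family: str,
    k: int,
    B: int = 100,
    seed: int = 0,
    fit_k: FitResult | None = None,
    fit_km1: FitResult | None = None,
    starts: StartPolicy | None = None,
    bootstrap_starts: StartPolicy | None = None,
    bootstrap_tol: float = 1e-5,
    bootstrap_max_iter: int = 500,
    **fit_kwargs,
) -> float:
    """Parametric bootstrap LRT of k-1 vs k classes.

    B datasets are drawn from the fitted (k-1)-class model; both class
    counts are refit on each and the null LR distribution is accumulated.
    p = (1 + #{LR_b >= LR_obs}) / (B + 1).  Deterministic given ``seed``.

    Bootstrap refits use a reduced start policy and a slightly looser
    tolerance (the convention for bootstrap draws, where only the LR
    exceedance matters); a draw whose refit fails to converge is redrawn
    once, then dropped with a warning.
    """
    if B < 19:
        raise ValueError("need B >= 19 bootstrap draws")
    y = np.asarray(data, dtype=float)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    if fit_km1 is None:
        fit_km1 = fit_em(data, family, k - 1, starts=starts, seed=seed, **fit_kwargs)
    if fit_k is None:
        fit_k = fit_em(data, family, k, starts=starts, seed=seed, **fit_kwargs)
    lr_obs = max(2.0 * (fit_k.loglik - fit_km1.loglik), 0.0)
    if bootstrap_starts is None:
        bootstrap_starts = StartPolicy(n_random=8, n_final=2, initial_iters=10)
    # bootstrap tolerance/cap take precedence over caller fit settings
    boot_kwargs = {
        k_: v for k_, v in fit_kwargs.items() if k_ not in ("tol", "max_iter")
    }
    exceed = 0
    used = 0
    for b in range(B):
        for attempt in range(2):  # one redraw on non-convergence, then drop
            draw_seed = int(rng.integers(0, 2**31 - 1))
            boot = sample_mixture(fit_km1.model, n, draw_seed)
            b1 = fit_em(
                boot, family, k - 1, starts=bootstrap_starts, seed=draw_seed,
                tol=bootstrap_tol, max_iter=bootstrap_max_iter, **boot_kwargs,
            )
            b2 = fit_em(
                boot, family, k, starts=bootstrap_starts, seed=draw_seed,
                tol=bootstrap_tol, max_iter=bootstrap_max_iter, **boot_kwargs,
            )
            if b1.converged and b2.converged:
                used += 1
                if 2.0 * (b2.loglik - b1.loglik) >= lr_obs:
                    exceed += 1
                break
        else:
            logger.warning("bootstrap draw %d dropped after one redraw", b)
    if used == 0:
        raise RuntimeError("no bootstrap draw converged")
    return (1.0 + exceed) / (used + 1.0)
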