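# Methods

## The model

Each mixture component g describes a linear latent growth process over p
occasions.  With loading matrix Λ = [1 | t] (time scores t = 0, …, p−1 by
default; configurable), factor means α⁽ᵍ⁾, factor covariance Ψ⁽ᵍ⁾ (2×2) and
diagonal residual covariance Θ⁽ᵍ⁾, the within-class location and scale are

    μ⁽ᵍ⁾ = Λ α⁽ᵍ⁾,        Σ⁽ᵍ⁾ = Λ Ψ⁽ᵍ⁾ Λ′ + Θ⁽ᵍ⁾.

The component distribution is the restricted multivariate skew t (rMST),

    Y = μ + δ|U₀| + U₁,

where W ~ Gamma(ν/2, ν/2), U₀ | W ~ N(0, 1/W) and U₁ | W ~ N_p(0, Σ/W)
share the scale-mixing variable W.  Marginalizing gives

    f(y) = 2 t_p(y; μ, Ω, ν) T₁(M(y); ν+p),       Ω = Σ + δδ′,
    M(y) = q(y)/√λ · √((ν+p)/(ν+d(y))),
    q(y) = δ′Ω⁻¹(y−μ),  d(y) = (y−μ)′Ω⁻¹(y−μ),  λ = 1 − δ′Ω⁻¹δ.

δ = 0 gives the multivariate t; ν → ∞ the skew normal; both the normal.
The four families therefore form a strictly nested ladder, and their
maximized log-likelihoods are directly comparable.  Note μ is a *location*,
not the mean: E[Y] = μ + δ·E|U₀|.

Two parameterization choices are exposed:

* `skew_structure`: `"observed"` (default) estimates δ as a free p-vector;
  `"factors"` constrains δ = Λδ_η (level and slope skew, 2 parameters).
* `class_varying`: `"all"` (default) gives every class its own
  α, Ψ, Θ, δ, ν; `"means"` reproduces the conventional
  mixture-software default in which only α and the weights differ by class
  and Ψ, Θ, δ, ν are pooled.

## Estimation

EM treats the class labels, the growth factors η, the skewing variable
|U₀| and the mixing variable W as missing data.

**E-step.**  Class posteriors come from the closed-form density.  Within a
class, the posterior of (U₀, W) given y factorizes as
U₀ | W, y ~ TN₍₀,∞₎(q, λ/W) and
p(w | y) ∝ w^{(ν+p)/2−1} e^{−w(ν+d)/2} Φ(q√(w/λ)), giving closed forms for

    e₁ = E[W|y],  e₂ = E[W U₀|y],  e₃ = E[W U₀²|y]

that require only univariate t CDF evaluations:
e₁ = ((ν+p)/(ν+d)) · T(M₂; ν+p+2)/T(M; ν+p) with M₂ the (ν+p+2)-rescaled
argument, e₂ = q·e₁ + √λ · Γ-ratio term, e₃ = λ + q·e₂ (the last identity
follows from the truncated-normal second moment).  These are verified in
the test suite against dense 2-D numerical integration of the latent
hierarchy.  Factor moments follow from the conditional normality of η
given (y, U₀, W).

**M-step.**  α, Ψ, Θ and (for `"observed"`) δ have closed-form updates
from additive per-class sufficient statistics; with `"factors"` the δ
update is a generalized-least-squares projection onto the loading space
using the previous Θ (a conditional-maximization step).  Under tied
(`"means"`) structure the Ψ/Θ/δ numerators are pooled across classes.

**Degrees of freedom.**  ν is updated by a bounded one-dimensional
maximization of the *observed* log-likelihood (an ECME conditional step,
every 5 EM iterations), with ν ∈ [2.1, 200]; fits at the upper bound are
effectively Gaussian.  The update keeps the likelihood monotone because
the current ν is retained whenever the optimizer cannot improve on it.

**Convergence and safeguards.**  Relative log-likelihood change below
1e−6 within a 1000-iteration cap (both configurable; Monte Carlo cells use
1e−5).  Class weights are floored at 1/n and residual variances at
10⁻⁶ of the data variance; a start that crosses these floors or produces a
singular scale matrix is discarded and logged.  Non-convergence is data,
never an exception.

**Starting values.**  A two-stage multistart: the base start (generating
parameters when known, otherwise moment-based; two-class starts use a
low/high factor-mean pattern, α = (0,0) and (1.5, 1.6)) plus, by default,
100 randomly perturbed starts run a short initial stage, and the best few
run to convergence.  The perturbation scatter is deliberately wide
(means shifted by ~2.5 factor-SDs, variances scaled by lognormal factors).
This matters scientifically: the spurious-class optima whose discovery
drives over-extraction rates lie far from moment-based starts, and we
observe that the located 2-vs-1-class likelihood ratio on null data grows
monotonically with search width and depth.  Any reported over-extraction
rate is therefore a property of *maximized* likelihoods only to the extent
the search is thorough; narrow searches understate it.

## The data generator

`generate_dataset` emulates a single-class population: solve the Fleishman
cubic-moment system for the target marginal skewness and excess kurtosis
("kurtosis" is excess kurtosis throughout), solve the Vale–Maurelli cubic
for each pairwise intermediate correlation, draw multivariate normal
deviates with that intermediate correlation matrix, apply the cubic
transform per column, and rescale to the growth model's implied means and
variances.  The defaults reproduce the study population: five occasions,
α = (1.00, 0.80), Ψ = [[1.00, 0.11], [0.11, 0.20]],
Θ = diag(1.00, 1.42, 2.25, 3.47, 5.09), conditions
(skew, ex. kurtosis) ∈ {(0,0), (1,2), (1.6,4)} and N ∈ {50, 200, 800, 3200}.

What the generator does *not* emulate: the transformed data have exactly
the requested margins and second-order structure but a Gaussian
dependence copula — they are **not** an rMST sample (nor any other
parametric family fitted here).  Every family is therefore misspecified
under the nonnormal conditions, which is precisely the regime the study
probes.  An alternative found in this literature injects the nonnormality
into the factors and residuals instead of the observed margins; that
dilutes the marginal skew/kurtosis and we do not use it (the observed
margins are the stated conditions).

## Enumeration criteria

AIC = −2LL + 2q, BIC = −2LL + q·ln n, SBIC = −2LL + q·ln((n+2)/24); the
smallest value wins, ties break toward fewer classes.  The VLMR statistic
2(LL_k − LL_{k−1}) is referred to a chi-square with 2·Δq degrees of
freedom — the long-standing rule of thumb for mixture LRTs, standing in
for the score-based weighted-chi-square reference whose weights require
per-observation information estimates; the LMR adjustment deflates the
statistic by c = 1 + 1/(Δq·ln n).  Like the original, the approximate test
is mildly anticonservative on null growth-mixture data (we measure ~0.1–0.2
at nominal 0.05, comparable to published behaviour of the real test).  The
BLRT refits both class counts on B parametric-bootstrap draws from the
fitted (k−1)-class model, p = (1 + #{LR_b ≥ LR_obs})/(B+1); bootstrap
refits use a reduced start policy and looser tolerance, matched between
observed and bootstrap fits so the comparison stays calibrated.  BLRT is
available for all four families.

## Monte Carlo design

`run_cell` runs replication r with seed = base_seed + r end-to-end
(generation, both fits, criteria), so cells are exactly reproducible and
independent of parallel worker count.  False-positive denominators count
only replications where both class counts converged; mean BIC per class
count averages over that count's converged replications.  The scaled-down
default profile uses R ≈ 30–100 replications per cell with a reduced
multistart (binomial error at R = 100: a true rate of 0.05 has 95% interval
≈ [0.01, 0.11]); the full factorial at R = 500 is a YAML flag away but is
a multi-day single-core computation.

Problem sizes used by the acceptance script: R = 100 for the normal-family
null cells, R = 50 for the N = 3200 cell and the BLRT calibration
(B = 99), R = 30 per skew-t grid cell, 10⁶ draws for generator validation,
and 400 replications for the mean-BIC summary.

## Known limitations and an honest discrepancy

* With every family misspecified (see above), the 2-vs-1-class likelihood
  gain grows linearly with N for *all* families, including the skew t.  At
  N = 50 (all conditions), at every N under the normal condition, and at
  N = 200 under mild nonnormality, the skew-t BIC error rate is 0.00–0.03
  and far below the normal family's, matching the reference study.  Under
  stronger nonnormality at N ≥ 200 (and mild nonnormality by N = 800),
  however, correctly maximized skew-t fits yield 2-class likelihood gains
  of ~50–330 points, and BIC rightly detects the misfit: the
  over-extraction rate rises toward 1.  The reference study reports 0.00 there, but its own mean-BIC
  tables imply a *negative* mean 2-vs-1-class LR for the skew t — two-class
  solutions worse than the one-class optimum they nest — which is only
  possible when the 2-class likelihood was not in fact maximized.  Our EM
  is monotone and starts 2-class fits at perturbations of the 1-class
  solution, so LR ≥ 0 by construction, and the uniform-0.00 pattern cannot
  be reproduced.  The qualitative ordering (skew t over-extracts least,
  normal most; BIC beats AIC/SBIC) is reproduced throughout.
* Over-extraction rates on null data depend on multistart thoroughness
  (see Starting values); they are lower bounds on the exact-ML rates.
* The VLMR/LMR reference distribution is an approximation (above).
* Estimation is point ML: no standard errors, no robust (sandwich)
  corrections.
* Quadratic growth, covariates, autoregressive residual structures and
  missing data are out of scope.
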