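# Methods

## The mixture model

Catch counts aggregated by fishing cruise are modeled as a two-state
mixture: with probability `1 − p_i` a cruise is in the zero-inflated
state and catches nothing; with probability `p_i` it is in the regular
state and the catch is Poisson with mean `μ_i`.  The observed-data
likelihood is

    L = Π_{y_i = 0} [(1 − p_i) + p_i e^{−μ_i}] · Π_{y_i > 0} p_i · Pois(y_i; μ_i)

with `log μ_i = log(effort_i) + β'x_i` and, for the unconstrained ZIGAM,
`logit p_i = γ'w_i`.  Throughout the package `p_i` is the probability of
the **regular** state; reports state this orientation.  The COZIGAM
replaces the free zero model by `logit p_i = α + δ·log μ_i`, coupling the
two processes on their link scales; `δ = 0` recovers a constant-p
mixture.

Assumptions: counts are conditionally Poisson given the regular state
(no overdispersion beyond zero inflation — negative-binomial or Tweedie
components are out of scope); cruises are independent given covariates;
effort acts proportionally on the count mean (hence the log-offset).

### EM fitting

A zero observation's state is unobserved, so the mixture is fitted by
EM.  The E-step computes the responsibility of the regular state for
each zero, `z_i = p_i e^{−μ_i} / ((1 − p_i) + p_i e^{−μ_i})` (`z_i = 1`
for positives); the M-step maximizes the expected complete-data
penalized log-likelihood, which separates into a `z`-weighted penalized
Poisson fit and a penalized binomial fit to the fractional
responsibilities.  Both inner fits are damped-Newton (penalized IRLS,
capped at 200 steps, tolerance 1e-12) warm-started from the previous
iteration, which makes the observed-data penalized log-likelihood
provably non-decreasing; the EM path is stored on the fitted model and
asserted monotone (tolerance 1e-8) in the tests.  EM stops when the
relative change falls below 1e-6 or after 250 iterations (the fitted
model then carries `converged_ = False`).  For the COZIGAM the M-step
profiles `(α, δ)` by a two-parameter logistic regression of the
responsibilities on `log μ̂`; because the count update ignores the
feedback of `μ` on `p`, strict monotonicity is not guaranteed for this
variant, though it holds in practice on all fixtures.

Degenerate inputs: a response without zeros makes the mixture collapse —
the fit falls back to a plain Poisson GAM with `p ≡ 1` and a structural
note.  An all-zero response is guarded by clipping every linear
predictor at ±30, which also protects against separation in the zero
model.

### Smooths

Smooth terms are low-rank thin-plate regression splines: the full
thin-plate system on knots at the unique covariate values (thinned to at
most 500 quantile knots) is eigen-truncated to its k leading components,
the polynomial-orthogonality constraint is absorbed into the basis, and
a sum-to-zero (column-centering) constraint makes each smooth
identifiable next to the intercept, leaving k − 1 columns per term.  The
wiggliness penalty is exactly zero on linear functions (rank k − 2 in
1-D, k − 3 in 2-D).  The shared year–month smooth of the SPT2 structure
is an isotropic 2-D thin-plate spline on coordinates standardized to
unit variance, which resolves the year/month scale mismatch; month is
treated non-cyclically.  Defaults: k = 10 (1-D), 25 (2-D) before
optimization; the SPT defaults are k_year = 5 (years take only seven
distinct values), k_month = 8, k_2d = 20.

### Laplace evidence (logE) and smoothing parameters

Model comparison and smoothing-parameter selection both use the
Laplace-approximated log marginal likelihood.  Each penalty `λ_j S_j` is
treated as a partially improper Gaussian prior whose normalizing
constant is taken on the penalty range space
(`+ ½[r_j log λ_j + log det⁺ S_j − r_j log 2π]`, with `r_j = rank S_j`);
unpenalized directions (intercepts, factor contrasts, null-space
columns, the COZIGAM linkage constants) carry flat priors.  The evidence
is then the penalized log-likelihood at the mode plus `½ p log 2π − ½
log det H`, with `H` the penalized Hessian.  For the mixtures, `H` is
block-approximated by the two components' penalized Hessians from the
final (responsibility-weighted) M-step.  The same conventions apply to
all three model classes, which is what makes their logE values
comparable; a one-parameter Poisson model's logE agrees with brute-force
quadrature within 0.1 in the tests.

No selection criterion for λ is inherent to the model, so λ is chosen by
maximizing this same logE: coordinate descent over a six-point
`log10 λ ∈ {−2, −0.5, 1, 2.5, 4, 5.5}` grid, at most two sweeps,
warm-started, with EM capped at 80 iterations during the search and the
full-precision EM rerun (cold-started) at the selected λ.  Keeping
selection and comparison on one scale avoids mixing criteria; the grid
is deliberately coarse — evidence surfaces in λ are flat near the
optimum and a finer search did not change any qualitative ordering.

### Fit summaries

Per-term effective degrees of freedom are the trace of the term's block
of the influence matrix `F = H⁻¹ X'WX`; the reference df uses the
`2F − F²` diagonal (slightly larger, as usual for penalized terms).
Wald χ² statistics use the Bayesian posterior covariance `H⁻¹`.
Explained deviance is computed on the mixture deviance
`2[l_sat − l_model]` (saturated: zeros contribute 0, positives the
saturated Poisson term) against an intercept-only null of the same model
class, and the adjusted coefficient of determination is
`R²_adj = 1 − [(n − 1)/(n − edf_total)]·(1 − dev_expl)` with
`edf_total` summing both components.  The exact formula used by the
original analysis library is not documented anywhere we could find, so
this definition is fixed here and stated; it is never compared against
published table values.

## Model selection workflow

* **Basis dimension**: per predictor, univariate zero-inflated fits over
  the k-grid {4, 6, 8, 10, 12}; highest logE wins, ties (within 1e-6)
  break toward smaller k.
* **Class adjudication**: GAM, ZIGAM and COZIGAM fitted univariately per
  predictor; failures are recorded as missing entries, never raised; the
  class winning the most predictors is chosen, ties resolving to ZIGAM.
* **ENV stepwise**: starting from the site factor plus offset, each step
  adds the candidate smooth with the largest logE gain among candidates
  not excluded (by the correlation screen) against anything already
  included; the search stops at the first step with no improvement, and
  the trace records every evaluation.  The site factor is always
  retained.

## Correlation screen

Pearson r with a Student-t test on n − 2 df and a Fisher-Z 95% interval,
plus Spearman s (average ranks for ties), on pairwise-complete rows.  A
pair is "problematic" when (i) p < 0.05, (ii) max(|CI|) ≥ 0.3, and
(iii) |s| ≥ 0.3 or min(|CI|) ≥ 0.3; flagged pairs never co-occur in one
model.  Two-sided p-values throughout; no multiple-testing correction
across pairs (deliberately, matching the screening protocol this
implements).

## Assemblage statistics

Sex-ratio goodness of fit is the uncorrected two-cell χ² (equivalently
`(m − f)²/n`); the published worked values (χ² = 2.098 for a 0.77:1
ratio of 122 sexed; 1.6897 for 0.78:1 of 116) reproduce exactly without
a continuity correction, which fixes that choice.  A reconstruction
utility recovers the unique integer split behind a rounded ratio by
exhaustive search and refuses ambiguous or impossible ratios — the
published tiger-shark line (0.69:1 of 56) admits no integer split and is
excluded from worked values.  Length comparisons use the Welch
two-sample t-test (safer than pooled-variance when only "2-sample
t-test" is specified) and Kruskal–Wallis with tie correction; the
post-hoc procedure compares mean-rank differences against
`z_{1−α/(k(k−1))}·√[N(N+1)/12·(1/n_i + 1/n_j)]`.

## The synthetic survey generator

The generator emulates the survey design: weekly cruises at two
nearshore sites (four 100-hook sets each, i.e. 400 hooks per cruise)
from September 2005 through December 2011 plus occasional 200-hook
mid-shelf sets — 518 + 38 cruises by default.  Covariates are drawn
through a Gaussian copula whose latent correlations are set from target
Spearman values via `r = 2 sin(πρ_s/6)`; the defaults reproduce the
published screen's strong pairs (temp–visib 0.60, visib–windspe −0.52,
visib–winddir −0.32, pluvio–winddir 0.35, tidamp–lunday −0.23,
windspe–winddir 0.19).  Temperature and solar radiation carry an annual
sinusoid injected into their latent normals (weights 0.6 / 0.4, peaking
in austral late summer); the affected latent correlations are inflated
to undo the seasonal dilution.  Margins map to realistic recorded
ranges (truncated normals; gamma for rainfall; uniform 1–30 for lunar
day).  Infeasible correlation targets raise a configuration error via a
Cholesky check.

Catches are drawn exactly as the model assumes (Bernoulli regular state,
then Poisson with the log-effort offset).  The default truth gives each
species a month sinusoid plus either a monotone temperature effect or a
quadratic tidal-amplitude effect in the count model — three distinct
shapes for recovery tests — and a zero model with its own month sinusoid
(amplitude 1.6, phase-shifted three months from the count seasonality,
i.e. in quadrature, so `p` varies with the environment but is not a
monotone function of `μ`) plus a lunar-day sinusoid.  This realizes the
regime the survey reported: strong zero inflation with a zero process
independent of the count mean, under which the unconstrained mixture
dominates both the plain GAM and the constrained variant.  Site effects
(log scale): nurse-like {PA −0.5, CS 0}, blacknose-like {PA −0.4,
CS 0.3}, tiger-like {PA −0.1, CS 1.0}, reflecting the reported spatial
patterns.  Per realization, each species' baseline log rate is
calibrated by scalar root-finding so the *expected* fraction of positive
cruises on that covariate table equals the published rate (16% / 9% /
6%); no abundance-scale parameters were ever published, so the
calibration targets are the only anchor.  Lengths are rejection-sampled
truncated normals with the published min/max/mean/sd; sexes are
Bernoulli with male fractions implied by the published ratios.

What the generator does **not** emulate: within-cruise set-level
structure, spatial point patterns inside sites, overdispersion beyond
zero inflation, measurement error in covariates, and temporal
autocorrelation beyond the seasonal signal.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not robustness to the ways real survey
data violate them.

## Problem sizes and numerical choices

The test suite and acceptance checks run the full 556-cruise design for
generation-only quantities (20 seeds) and for the evidence-ordering
checks; fitting-heavy property tests use 200–2000 observations and 3–10
seeds, sizes at which the checked orderings are already stable.  The
pipeline smoke test runs a reduced 132-cruise scenario.  Linear
predictors are clipped at ±30; penalty matrices are eigenvalue-clipped
at zero after truncation; singular Hessians in the evidence are
ridge-stabilized with a warning.  Ties in stepwise selection resolve to
the first candidate evaluated; the stepwise stops at the first
non-improving step.

## Known limitations

* The COZIGAM linkage `(α, δ)` is weakly identified when `log μ` has a
  narrow range or the regular state is rare; recovery to ±0.3 needs
  n ≈ 2000 with a well-spread count mean.
* The mixture evidence uses a block-diagonal Hessian approximation that
  ignores the cross-information between components carried by the zero
  observations; orderings are insensitive to this in all checks, but
  absolute logE values are approximate.
* `R²_adj` and the reference df follow the definitions above and are not
  exchangeable with other software's versions of those diagnostics.
* Partially-constrained variants (coupling only some covariates) and
  negative-binomial/Tweedie regular components are out of scope.
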