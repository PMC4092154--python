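# zicpue

Zero-inflated generalized additive modeling of catch-per-unit-effort for
longline shark surveys, built around the analysis protocol of the 8-year
fisheries-independent survey off Recife, northeastern Brazil.

## The problem

Counting sharks caught per fishing cruise produces data dominated by
zeros: most cruises catch nothing, both because sharks are genuinely
absent (a structural zero) and because a Poisson count process at a low
rate often produces zero.  A plain Poisson GAM conflates the two.  This
package models the catch `y_i` of a cruise as a mixture

    y_i = 0                with probability 1 − p_i
    y_i ~ Poisson(μ_i)     with probability p_i

    log μ_i  = log(effort_i) + Σ_j f_j(x_ij) + site effects   (count model)
    logit p_i = Σ_k g_k(w_ik)                                 (zero model)

where `p_i` is the probability of the *regular* (non-zero-inflated)
state, the `f_j`, `g_k` are penalized thin-plate regression splines, and
the log of fishing effort (deployed hooks) enters as an offset so the
fitted mean is a standardized catch rate (CPUE).  Three model classes are
supported:

* **GAM** — plain Poisson (no zero inflation);
* **ZIGAM** — the mixture above, fitted by EM because the state of a zero
  observation is unobserved (capped at 250 iterations);
* **COZIGAM** — the constrained variant `logit p_i = α + δ·log μ_i`,
  which couples the two processes.

Models are compared and built with the Laplace-approximated log marginal
likelihood (**logE**): class adjudication (GAM vs ZIGAM vs COZIGAM),
per-predictor basis-dimension choice, the spatiotemporal structures SPT1
(site factor + independent year and month smooths) vs SPT2 (site factor +
one shared bivariate year–month smooth), and forward stepwise selection
of environmental covariates under correlation-screen exclusions
(Pearson r with Fisher-Z intervals, Spearman s, and a three-criterion
rule at the 0.3 threshold).  Assemblage composition statistics (sex-ratio
χ² tests, sex-by-period contingency tests, Welch t-tests and
Kruskal–Wallis tests on total lengths with a mean-rank post-hoc
procedure) round out the pipeline.

The original survey data were never deposited, so the package ships a
synthetic survey generator (`zicpue.simulate`) with fully known truth —
copula-correlated environmental covariates, zero-inflated catches
calibrated to the published positive-catch rates (16% / 9% / 6% for the
nurse-, blacknose- and tiger-like species), and length/sex composition
matching the published summaries — against which every pipeline stage is
tested, including parameter recovery.

## Worked example

```python
from zicpue import (default_scenario, ModelSpec, fit_zigam,
                    summarize_fit, log_marginal_likelihood)
from zicpue.selection import site_effect_tests

survey = default_scenario(1)          # 518 nearshore + 38 mid-shelf cruises
spec = ModelSpec(
    "ZIGAM", "count_ginglymostoma cirratum",
    smooth_terms=(("month", 8), ("temp", 8)),
    factor_terms=(("site", "BV"),),
)
fit = fit_zigam(spec, survey.cruises)
print(summarize_fit(fit).round(3).to_string(index=False))
print(f"logE = {log_marginal_likelihood(fit):.2f}")
print(site_effect_tests(fit).round(3).to_string(index=False))
```

prints

```
    term   edf  ref_df  chi_sq  p_value  r2_adj  dev_expl
    site 2.000   2.000   8.813    0.012   0.161     0.179
s(month) 1.001   1.001  10.214    0.001   0.161     0.179
 s(temp) 1.000   1.000   3.763    0.052   0.161     0.179
logE = -284.70
level reference   coef    se      z  p_value
   CS        BV -0.049 0.403 -0.121    0.904
   PA        BV -0.553 0.189 -2.928    0.003
```

Reading this: each smooth term's effective degrees of freedom (edf),
Wald χ² and p-value; the model explains 17.9% of the mixture deviance
with an adjusted R² of 0.161 on this synthetic realization.  The site
contrasts show the PA site with a significantly lower catch rate than the
BV reference (Z = −2.93, p = 0.003) — the generating truth gives PA a
−0.5 log-scale effect — while the mid-shelf CS effect is indistinguishable
from BV, matching its true value of 0.

A command-line interface wraps the stages:

```sh
zicpue simulate --seed 1 --outdir survey/
zicpue screen survey/cruise_table.csv
zicpue fit survey/cruise_table.csv --species "galeocerdo cuvier" --smooth tidamp:8
zicpue report --config run.yaml      # full pipeline, seven report files
```

## Layout

| module | role |
|---|---|
| `zicpue.io` | set/capture table reading, filtering, cruise-level aggregation |
| `zicpue.simulate` | synthetic survey generator with known truth |
| `zicpue.splines` | low-rank thin-plate regression spline bases |
| `zicpue.glm` | penalized IRLS engine (Poisson / binomial) |
| `zicpue.zigam` | GAM / ZIGAM / COZIGAM estimators, logE, summaries |
| `zicpue.screening` | covariate correlation screen |
| `zicpue.selection` | k optimization, class adjudication, SPT specs, stepwise ENV |
| `zicpue.assemblage` | sex-ratio, contingency, length and post-hoc tests |
| `zicpue.pipeline` / `zicpue.cli` | end-to-end runs and the `zicpue` command |

See `docs/methods.md` for the statistical details and design choices.
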