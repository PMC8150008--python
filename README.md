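# swip — similarity-weighted informative priors for Bayesian regression

Researchers who want to use results of previously conducted studies as an
informative prior for a new ("focal") regression analysis face a problem:
previous studies differ in their samples, their outcomes and their
circumstances, so not all of them should contribute equally. `swip`
quantifies that heterogeneity, turns it into a per-coefficient similarity
weight, and uses the weight to discount the informative prior — a
direct, evidence-based alternative to the power prior and the
meta-analytic predictive (MAP) prior. It is aimed at applied
psychologists, education researchers and biostatisticians running
Bayesian multiple regressions with historical data at hand.

## The similarity measure and the weighted prior

Three components are estimated from the focal study and the K previous
studies:

- **B̄** — a propensity-score generalizability index. For each previous
  study, a logistic model predicts membership in the focal sample from
  the covariates; B_k is the Bhattacharyya overlap ∫√(f_f f_p) of the two
  score densities (Gaussian KDE with a Sheather–Jones bandwidth), and
  B̄ = (1/K)Σ B_k. B̄ = 1 for indistinguishable samples, 0 for disjoint
  ones.
- **τ²** — between-study heterogeneity of Fisher-z partial-correlation
  effect sizes, from a hierarchical Bayesian random-effects meta-analysis
  (one per predictor).
- **δτ²** — heterogeneity explained by study-level moderators:
  δτ² = max(0, τ² − τ²_res), with τ²_res the residual variance of the
  mixed-effects meta-analysis.

They combine into the per-predictor similarity measure

    ω_p = B̄ · L / (1 + exp[ s · (τ² + δτ² − m) ]),   L = 1, m = 0.24, s = 10,

a logistic decline in total heterogeneity scaled by sample overlap. ω is
non-compensatory: high sample similarity cannot offset heterogeneous
outcomes, and vice versa. The focal regression y ~ N(β₀ + Xβ, σ²) with
β₀ ~ N(0, 10) and σ ~ half-Cauchy(0, 2.5) then receives

    β_p ~ N(μ_p, SE_p²)^{ω_p}  ≡  N(μ_p, SE_p² / ω_p),

where μ_p and SE_p are the meta-analytic mean and its standard error. At
ω = 1 the prior is used fully; as ω → 0 it flattens to non-informative.
Comparator arms — pooled analysis, normalized power prior (conjugate
normal-inverse-gamma with uniform random a₀), and the robustified MAP
prior — plus the full simulation study (210 design conditions) are
included.

## Worked example

```python
from swip import (DEFAULT_TRUE_PARAMS, McmcConfig, SimCondition,
                  generate_focal, generate_database, generalizability_index,
                  effect_sizes, mixed_effects_meta, records_for_predictor,
                  similarity_weights, prior_from_meta, fit_swip)

cond = SimCondition(K=5, delta_N=-100, delta_mu=0.5, tau2=0.05, n_reps=1, seed=7)
focal = generate_focal(DEFAULT_TRUE_PARAMS, seed=1)
db = generate_database(cond, DEFAULT_TRUE_PARAMS, seed=2)

gen = generalizability_index(focal, db)
records = effect_sizes(db)
cfg = McmcConfig(seed=3)           # 4 chains x 2,000 iterations, 1,000 burn-in
summaries = [mixed_effects_meta(records_for_predictor(records, j + 1),
                                db.moderators, cfg) for j in range(focal.p)]
weights = similarity_weights(summaries, gen)
fit = fit_swip(focal, prior_from_meta(summaries, weights.omega_p), cfg)
```

Output:

```
B_bar = 0.896
x1: tau2=0.1082 delta_tau2=0.0000 mu_z=0.271 omega=0.707
x2: tau2=0.1904 delta_tau2=0.0000 mu_z=-0.119 omega=0.557
x3: tau2=0.0675 delta_tau2=0.0000 mu_z=0.359 omega=0.761
        mean     sd   rhat       ess
beta0 -0.111  0.083  1.000  4053.376
beta1  0.500  0.078  1.001  4086.057
beta2  0.206  0.080  1.000  3926.740
beta3 -0.381  0.073  1.001  3725.736
sigma  1.107  0.058  1.001  3583.527
```

The five previous studies overlap well with the focal sample
(B̄ = 0.90) but carry moderate outcome heterogeneity, so the weights land
between 0.56 and 0.76. The focal data were generated with
β = (0.5, 0.25, −0.5) while the previous studies scatter around
(0.4, 0.0, 0.3): the posterior means show the characteristic partial
shrinkage toward the meta-analytic means — most visibly β₃, pulled from
−0.5 toward 0.3 to −0.38 — with every R̂ ≈ 1.

A `swip` command-line tool mirrors the pipeline
(`swip simulate | similarity | meta | omega | fit | run-study`).

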