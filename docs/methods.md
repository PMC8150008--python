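# Methods

This note documents the statistical models implemented in `swip`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the method
description left room.

## Sample overlap: the generalizability index B̄

For each (focal, previous) pair of samples, a logistic regression of
the membership indicator Z (1 = focal) on the p covariates yields
sampling propensity scores s(X) = Pr(Z = 1 | X). The per-study index is
the Bhattacharyya coefficient of the two score densities,

    B_k = ∫₀¹ √( f_f(s) · f_p(s) ) ds,

estimated by Gaussian-kernel density estimation on a fixed 512-point
grid over [0, 1], with each density renormalized to integrate to one on
the grid before the trapezoidal quadrature; the result is clamped to
[0, 1]. B̄ is the unweighted mean over the K previous studies. The
square-root (Bhattacharyya) form is used because it alone attains 1 for
identical densities and 0 for disjoint ones; the plain product form
∫ f_f f_p, which appears in some descriptions of the index, is exposed
behind `product_form=True` but is not a bounded similarity coefficient.

Bandwidths come from a Sheather–Jones solve-the-equation plug-in
selector (`bw_method="sj"`, the default), computed on a 512-bin linear
binning of the data so the pairwise sums cost O(bins²) regardless of
sample size, with Silverman's rule as the fallback for tiny (< 10
observations) or degenerate samples; zero-variance samples receive a
minimal positive bandwidth with a warning. Near-perfect separation of
the two samples — the legitimate signature of highly dissimilar
samples — triggers an L2-penalized logistic fit (C = 10) instead of an
error, since B → 0 is an informative outcome. Collinear covariate
columns are dropped via pivoted QR with a warning. Fitted scores are
clipped to [1e−6, 1 − 1e−6]. The outcome variable is not part of the
propensity covariates.

## Heterogeneity: Fisher-z meta-analysis

Each previous study's OLS fit (with intercept) is converted to partial
correlations per predictor, r_j = t_j / √(t_j² + df) with
df = n − p − 1, then to Fisher-z effect sizes z = atanh(r) with known
sampling variance v = 1/(n − q − 3), q = p − 1 partialled covariates.
Correlations at the numerical boundary are clamped to |r| = 1 − 1e−8
with a warning.

The random-effects model per predictor is

    z_k ~ N(θ_k, v_k),  θ_k ~ N(μ, τ²),  μ ~ N(0, 10),  τ ~ half-N(0.5),

and the mixed-effects model adds the study-level moderator (with
intercept) to the mean structure. The hyperpriors are weakly
informative on the z scale and stable down to K = 3; both are
configurable. Point estimates are the posterior mean/SD for μ (the
prior hyperparameters μ_p, SE_p) and the posterior median for variance
components, whose posteriors are right-skewed. The moderator-explained
heterogeneity is δτ² = max(0, τ² − τ²_res), computed from the two
models' independent posterior medians, so δτ² = 0 exactly whenever
τ²_res ≥ τ².

Because θ and the mean coefficients are conditionally Gaussian, they
are integrated out analytically; the remaining one-dimensional
posterior of τ² is evaluated by deterministic quadrature on a
1025-point uniform τ grid (spanning 0 to max(4 · prior scale,
3 · SD(z) + 0.5)) and sampled exactly by inverse-CDF with within-cell
jitter, after which μ (and the moderator slope) are drawn from their
conjugate normals. The draws are therefore independent — there is no
Markov chain to converge — but the Gelman–Rubin diagnostic is still
computed on pseudo-chains so every fitted object honours the same
convergence contract (R̂ < 1.02). `McmcConfig` controls the number of
draws (chains × post-warmup iterations).

## The similarity measure ω

    ω_p = B̄ · L / (1 + exp[ s · (τ²_p + δτ²_p − m) ]),

with defaults L = 1, midpoint m = 0.24 and slope s = 10 frozen in
`OmegaConfig`. The midpoint sits at the upper end of the heterogeneity
range typical of psychological research and the slope makes the
logistic discriminate sharply across τ² + δτ² ∈ (0, 0.5]. ω ∈ [0, 1],
is linear in B̄, strictly decreasing in total heterogeneity, and
non-compensatory (ω ≤ B̄ and ω ≤ the logistic factor). The parameters
are exposed for sensitivity analysis but never adapted to data.

## Regression arms

All arms share the likelihood y ~ N(β₀ + Xβ, σ²) with β₀ ~ N(0, 10)
and σ ~ half-Cauchy(0, 2.5). Every N(a, b) in this package reads b as
a variance. The half-Cauchy is placed on the SD σ, the standard
practice in applied Bayesian regression workflows.

- **SWIP**: β_j ~ N(μ_j, SE_j²)^{ω_j}, implemented exactly as
  N(μ_j, SE_j²/ω_j). Below ω_floor = 1e−3 the powered prior is
  effectively flat and is replaced by the proper diffuse N(0, 100).
- **Pooled**: all rows of the focal and previous studies stacked, with
  non-informative N(0, 100) slope priors.
- **MAP**: per predictor, the predictive distribution of a new study's
  effect, N(μ_j, SE_j² + τ²_j), robustified as a two-component mixture
  with a diffuse N(0, 100) component of weight 0.2 (the conventional
  default; configurable).
- **NPP**: normalized power prior with random a₀ ~ uniform(0, 1)
  discretized on a 21-point grid. The baseline prior is a diffuse
  normal-inverse-gamma (slope variance 100σ², intercept 10σ²,
  IG(0.01, 0.01)); for each a₀ the a₀-powered historical likelihood
  yields a proper NIG prior in closed form, the posterior over a₀ is
  proportional to the focal-data marginal likelihood, and the final
  posterior is the exact finite mixture of conjugate NIG posteriors.

**Scale bridge.** The meta-analytic μ, SE and τ² live on the Fisher-z
scale; the prior is placed on raw coefficients. The mean back-transforms
via tanh, and SE and τ use the delta method (factor 1 − r², squared for
variances). With standardized predictors and unit error variance — as
in the simulation design — partial correlations approximate the raw
coefficients, so the r-scale values serve directly as coefficient-scale
hyperparameters.

**Sampling.** SWIP, pooled and MAP use a blocked Gibbs sampler,
vectorized across chains: the coefficient block is conjugate
multivariate normal given σ²; the half-Cauchy scale uses the
inverse-gamma auxiliary-variable representation (σ² | a ~ IG(½, 1/a),
a ~ IG(½, 1/A²)), so every update is an exact conditional draw; the MAP
mixture adds per-coefficient component indicators. Chains start from
overdispersed perturbations of the OLS solution. Defaults are 4 chains
of 2,000 iterations with 1,000 burn-in; rank-normalized split-R̂ and
bulk ESS are reported for every parameter, a fit whose worst R̂ exceeds
1.02 is retried once with doubled iterations and flagged if still
non-convergent. The NPP posterior is sampled independently (it is a
finite mixture of closed forms) and reports the same diagnostics via
pseudo-chains. A `sigma_fixed` option freezes σ for closed-form
verification.

## The synthetic-data generator

The generator reproduces the simulation design: a focal study with
N_F = 200, β_F = (0.5, 0.25, −0.5), standard-normal predictors and unit
error variance; K previous studies whose sample sizes are drawn from
N(N_F + Δ_N, variance 25) rounded and floored at p + 4, whose
predictors are N(Δ_μ, 1), and whose coefficient vectors are

    β_k = μ_β + γ m_k 1 + e_k,   γ = √(r² τ²),   e_k ~ N(0, τ² I),

with μ_β = (0.4, 0.0, 0.3), moderator m_k ~ N(0, 1) and r² = 0.1. The
moderator thus adds explained variance on top of τ²: the total
coefficient variance is (1 + r²) τ² — matching the design's printed
totals τ² + δτ² = 1.1 τ² (0.0275 for τ² = 0.025, …) — with residual
variance τ² after controlling the moderator. An alternative reading
(total τ², residual 0.9 τ²) exists; the printed totals fix the choice.
Coefficient coordinates are drawn independently (diagonal covariance),
the same mean offset Δ_μ applies to all predictors, and generating
intercepts are 0. The full factorial grid (3 × 2 × 5 × 7 levels,
100 replications) gives 210 conditions and 21,000 datasets.

What the generator does *not* emulate: non-normal predictors or errors,
missing data, varying p across studies, unequal within-study error
variances, correlated predictors, or publication-selected study sets.
Passing tests therefore demonstrate correct behavior under the idealized
design, not robustness to those real-data features.

Seeding is splittable: each grid condition receives a child seed from
`SeedSequence([base_seed, index])`, and each replication derives
per-consumer streams (data, database, each model fit) from
`SeedSequence([condition_seed, rep, stream])`, so conditions and
replications are reproducible independently and in any execution order.

## Study runner and evaluation

Per replication the runner generates the data, computes B̄, runs the
per-predictor meta-analyses, forms ω and the prior, and fits the
requested arms; replication-level crashes are logged and excluded with
counts. Aggregation follows the evaluation criteria: estimates averaged
over replications, standard errors as √(mean SE²), and shrinkage
defined as β̂ − β_F — positive when the meta-analytic mean lies above
the true focal value and pulls the estimate up, negative when below —
which reproduces the documented direction of shrinkage for each
coefficient. `behavior_models` fits two OLS summaries: mean ω on the
design's total heterogeneity and Δ_μ (both slopes negative), and mean
|shrinkage| of the SWIP arm on mean ω (slope positive).

The scaled-down verification study used by the test suite and
`scripts/acceptance.py` runs 8 conditions spanning the corners of the
design grid (the even-parity half fraction of the 2⁴ corner cube over
K ∈ {3, 10}, Δ_N ∈ {−100, 100}, Δ_μ ∈ {0.25, 3}, τ² ∈ {0.025, 0.5})
with 5 replications and all four arms at the full sampler settings —
160 regression fits plus 240 meta-analytic fits — a problem size chosen
to exercise every code path across the grid's extremes while remaining
quick on a single CPU.

## Known limitations

- The coefficient-scale bridge from Fisher-z summaries is exact only
  for standardized predictors with unit error variance; for raw-scale
  applications, meta-analyze raw coefficients instead and supply the
  prior directly via `PriorSpec`.
- δτ² couples two independently fitted posterior medians; with very
  small K the truncation at zero is frequently active.
- B̄ requires raw covariate data from the previous studies;
  summary-data-only settings are out of scope.
- The NPP arm implements the random-a₀, uniform-prior reading with a
  conjugate closed form; non-conjugate likelihoods would require
  marginal-likelihood estimation that this package deliberately avoids.
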