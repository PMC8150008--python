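"""Fisher-z effect sizes and hierarchical Bayesian meta-analysis.

Per-study regressions are converted to partial-correlation effect
sizes on the variance-stabilized Fisher-z scale, then pooled with a
random-effects model (pooled mean mu, between-study variance tau2) and
a mixed-effects model that adds a study-level moderator to the mean
structure (residual variance tau2_res).  The moderator-explained
heterogeneity is delta_tau2 = max(0, tau2 - tau2_res).

The hierarchical models are z_k ~ N(theta_k, v_k), theta_k ~ N(w_k'b,
tau2) with b ~ N(0, 10 I) and tau ~ half-normal(0.5).  Because the
study effects and the mean parameters integrate out analytically, the
posterior of tau2 is one-dimensional; it is evaluated by deterministic
quadrature on a fine tau grid and sampled exactly, then b | tau2 is
drawn from its conjugate normal.  The draws are therefore independent;
the convergence diagnostic is computed on pseudo-chains so every fit
honours the same reporting contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mcmc import McmcConfig, chunk_chains, rhat
from .simgen import StudyDatabase

__all__ = [
    "EffectSizeRecord",
    "HeterogeneitySummary",
    "effect_sizes",
    "records_for_predictor",
    "random_effects_meta",
    "mixed_effects_meta",
]

_R_CLAMP = 1.0 - 1e-8
_TAU_GRID_SIZE = 1024


@dataclass(frozen=True)
class EffectSizeRecord:
    """One study's partial correlation for one predictor, on the z scale."""

    study_id: str
    predictor_index: int  # 1-based
    r_partial: float
    z: float
    v: float
    n: int


@dataclass
class HeterogeneitySummary:
    """Pooled effect and heterogeneity decomposition for one predictor."""

    predictor_index: int
    mu_z: float
    se_z: float
    tau2: float
    tau2_res: float = np.nan
    delta_tau2: float = np.nan
    tau2_ci95: tuple = (np.nan, np.nan)
    max_rhat: float = np.nan
    converged: bool = True
    tau2_draws: np.ndarray = field(default=None, repr=False)


def effect_sizes(db: StudyDatabase) -> list:
    """Per-study, per-predictor Fisher-z partial correlations.

    From each study's OLS fit (with intercept): r_j = t_j / sqrt(t_j^2 +
    df) with df = n - p - 1, z = atanh(r), sampling variance
    v = 1/(n - q - 3) with q = p - 1 covariates partialled out.
    """
    out = []
    for ds in db.studies:
        n, p = ds.n, ds.p
        if n <= p + 4:
            raise ValueError(f"study {ds.study_id}: n must exceed p + 4")
        Xa = np.column_stack([np.ones(n), ds.X])
        G = Xa.T @ Xa
        coef = np.linalg.solve(G, Xa.T @ ds.y)
        resid = ds.y - Xa @ coef
        df = n - p - 1
        s2 = resid @ resid / df
        se = np.sqrt(s2 * np.diag(np.linalg.inv(G)))
        t = coef / se
        v = 1.0 / (n - (p - 1) - 3)
        for j in range(p):
            r = t[j + 1] / np.hypot(t[j + 1], np.sqrt(df))
            if abs(r) >= _R_CLAMP:
                import warnings

                warnings.warn("partial correlation at boundary; clamped", stacklevel=2)
                r = np.sign(r) * _R_CLAMP
            out.append(
                EffectSizeRecord(
                    study_id=ds.study_id,
                    predictor_index=j + 1,
                    r_partial=float(r),
                    z=float(np.arctanh(r)),
                    v=v,
                    n=n,
                )
            )
    return out


def records_for_predictor(records, j: int) -> list:
    return [r for r in records if r.predictor_index == j]


# ---------------------------------------------------------------------------
# Marginal likelihood of z given tau2, with mean coefficients b ~ N(0, Vb I)
# integrated out: z ~ N(0, D + Vb W W'), D = diag(v + tau2).

def _log_marginal(z, v, W, tau2_grid, prior_b_var):
    K, q = W.shape
    d = v[None, :] + tau2_grid[:, None]  # (G, K)
    zd = z[None, :] / d
    Wd = W[None, :, :] / d[:, :, None]  # (G, K, q)
    A = np.eye(q)[None] / prior_b_var + np.einsum("gkp,kq->gpq", Wd, W)
    rhs = np.einsum("gkp,k->gp", Wd, z)
    L = np.linalg.cholesky(A)
    u = np.linalg.solve(L, rhs[:, :, None])[:, :, 0]
    logdet_A = 2.0 * np.log(np.einsum("gii->gi", L)).sum(axis=1)
    quad = (zd * z[None, :]).sum(axis=1) - (u**2).sum(axis=1)
    logdet = np.log(d).sum(axis=1) + logdet_A + q * np.log(prior_b_var)
    return -0.5 * (K * np.log(2 * np.pi) + logdet + quad)


def _sample_posterior(z, v, W, mcmc, prior_b_var, prior_tau_scale, seed):
    """Exact draws of (b, tau2) from the marginalized posterior."""
    z = np.asarray(z, float)
    v = np.asarray(v, float)
    K, q = W.shape
    rng = np.random.default_rng(seed)

    tau_max = max(4.0 * prior_tau_scale, 3.0 * np.std(z) + 0.5)
    tau_grid = np.linspace(0.0, tau_max, _TAU_GRID_SIZE + 1)
    tau_mid = 0.5 * (tau_grid[:-1] + tau_grid[1:])
    dtau = tau_grid[1] - tau_grid[0]

    log_post = _log_marginal(z, v, W, tau_mid**2, prior_b_var)
    log_post += -0.5 * (tau_mid / prior_tau_scale) ** 2  # half-normal prior on tau
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()

    n_draws = mcmc.chains * mcmc.kept
    cells = rng.choice(tau_mid.size, size=n_draws, p=w)
    tau = tau_grid[cells] + dtau * rng.random(n_draws)
    tau2 = tau**2

    # b | tau2 conjugate normal; only the pooled-mean coordinate is reported
    d = v[None, :] + tau2[:, None]
    Wd = W[None, :, :] / d[:, :, None]
    A = np.eye(q)[None] / prior_b_var + np.einsum("skp,kq->spq", Wd, W)
    rhs = np.einsum("skp,k->sp", Wd, z)
    L = np.linalg.cholesky(A)
    mean_b = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    eps = rng.standard_normal((n_draws, q, 1))
    b = mean_b + np.linalg.solve(np.transpose(L, (0, 2, 1)), eps)[:, :, 0]
    return b, tau2


def _fit(z, v, W, mcmc, prior_b_var, prior_tau_scale, seed, predictor_index):
    b, tau2 = _sample_posterior(z, v, W, mcmc, prior_b_var, prior_tau_scale, seed)
    mu = b[:, 0]
    rh = max(
        rhat(chunk_chains(mu, mcmc.chains)), rhat(chunk_chains(tau2, mcmc.chains))
    )
    return HeterogeneitySummary(
        predictor_index=predictor_index,
        mu_z=float(mu.mean()),
        se_z=float(mu.std(ddof=1)),
        tau2=float(np.median(tau2)),
        tau2_ci95=(float(np.quantile(tau2, 0.025)), float(np.quantile(tau2, 0.975))),
        max_rhat=rh,
        converged=bool(rh < mcmc.rhat_threshold),
        tau2_draws=tau2,
    )


def _extract(records):
    if len(records) < 2:
        raise ValueError("random-effects meta-analysis needs K >= 2 studies")
    z = np.array([r.z for r in records])
    v = np.array([r.v for r in records])
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    idx = records[0].predictor_index
    return z, v, idx


def random_effects_meta(
    records,
    mcmc: McmcConfig = McmcConfig(),
    prior_mu_var: float = 10.0,
    prior_tau_scale: float = 0.5,
    seed: int | None = None,
) -> HeterogeneitySummary:
    """Random-effects model: posterior of the pooled mean and tau2.

    Returns the posterior mean/SD of mu (reported as mu_z / se_z) and
    the posterior median of tau2; tau2_res and delta_tau2 are left
    unset.
    """
    z, v, idx = _extract(records)
    W = np.ones((z.size, 1))
    return _fit(
        z, v, W, mcmc, prior_mu_var, prior_tau_scale,
        mcmc.seed if seed is None else seed, idx,
    )


def mixed_effects_meta(
    records,
    moderators,
    mcmc: McmcConfig = McmcConfig(),
    prior_mu_var: float = 10.0,
    prior_tau_scale: float = 0.5,
    seed: int | None = None,
) -> HeterogeneitySummary:
    """Mixed-effects model with one moderator; complete heterogeneity summary.

    The moderator (with intercept) enters the mean structure; tau2_res
    is the posterior median residual variance, and delta_tau2 =
    max(0, tau2 - tau2_res) with tau2 taken from the random-effects
    model on the same records (the truncation-at-zero rule).
    """
    z, v, idx = _extract(records)
    m = np.asarray(moderators, dtype=float)
    if m.shape[0] != z.size:
        raise ValueError("moderators must align with records")
    base_seed = mcmc.seed if seed is None else seed
    re = random_effects_meta(
        records, mcmc, prior_mu_var, prior_tau_scale, seed=base_seed
    )
    W = np.column_stack([np.ones(z.size), m])
    mix = _fit(z, v, W, mcmc, prior_mu_var, prior_tau_scale, base_seed + 1, idx)
    tau2_res = mix.tau2
    return HeterogeneitySummary(
        predictor_index=idx,
        mu_z=re.mu_z,
        se_z=re.se_z,
        tau2=re.tau2,
        tau2_res=tau2_res,
        delta_tau2=max(0.0, re.tau2 - tau2_res),
        tau2_ci95=re.tau2_ci95,
        max_rhat=max(re.max_rhat, mix.max_rhat),
        converged=re.converged and mix.converged,
        tau2_draws=re.tau2_draws,
    )
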