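"""Orchestration of the simulation study and its evaluation criteria.

Runs conditions x replications x analysis arms, collecting per-fit
posterior summaries, the similarity components (B-bar, tau2,
delta_tau2, omega) and the shrinkage of each coefficient toward its
meta-analytic mean.  Aggregation follows the study's evaluation
criteria: estimates averaged over replications, standard errors as the
root of the mean squared SE, and simple linear models describing how
omega responds to heterogeneity and predictor overlap, and how
shrinkage responds to omega.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .generalizability import generalizability_index
from .meta_analysis import effect_sizes, mixed_effects_meta, records_for_predictor
from .mcmc import McmcConfig
from .regression_models import (
    PriorSpec,
    fit_map,
    fit_npp,
    fit_pooled,
    fit_swip,
    prior_from_meta,
)
from .similarity import OmegaConfig, similarity_weights
from .simgen import (
    DEFAULT_TRUE_PARAMS,
    SimCondition,
    TrueParams,
    generate_database,
    generate_focal,
    replication_seed,
    total_heterogeneity,
)

__all__ = [
    "ConditionResult",
    "ALL_ARMS",
    "shrinkage",
    "run_condition",
    "run_study",
    "behavior_models",
    "count_datasets",
    "grid_corner_conditions",
]

logger = logging.getLogger("swip")

ALL_ARMS = ("pooled", "npp", "map", "swip")


@dataclass
class ConditionResult:
    """Aggregated outcome of all replications of one design condition."""

    condition: SimCondition
    n_completed: int
    n_failed: int
    max_rhat: float
    summary: pd.DataFrame      # per (arm, coefficient): mean estimate, avg SE, shrinkage
    components: pd.DataFrame   # per predictor: mean omega, B_bar, tau2, delta_tau2
    replications: pd.DataFrame = field(repr=False, default=None)

    @property
    def mean_omega(self) -> float:
        return float(self.components["mean_omega"].mean())


def shrinkage(beta_true: float, beta_hat: float) -> float:
    """Displacement of the estimate away from the focal-study true value.

    Positive when the posterior mean exceeds the true coefficient; a
    prior mean above the true value pulls the estimate up and produces
    positive shrinkage, one below pulls it down (negative).
    """
    if not (np.isfinite(beta_true) and np.isfinite(beta_hat)):
        raise ValueError("shrinkage requires finite inputs")
    return float(beta_hat - beta_true)


def _run_replication(cond, true_params, arms, mcmc, omega_config, rep):
    focal = generate_focal(true_params, replication_seed(cond, rep, 0))
    db = generate_database(cond, true_params, replication_seed(cond, rep, 1))
    gen = generalizability_index(focal, db)
    records = effect_sizes(db)
    meta_cfg = McmcConfig(
        chains=mcmc.chains,
        iterations=mcmc.iterations,
        warmup=mcmc.warmup,
        rhat_threshold=mcmc.rhat_threshold,
        seed=replication_seed(cond, rep, 2),
    )
    summaries = [
        mixed_effects_meta(
            records_for_predictor(records, j + 1), db.moderators, meta_cfg,
            seed=replication_seed(cond, rep, 3 + j),
        )
        for j in range(focal.p)
    ]
    weights = similarity_weights(summaries, gen, omega_config)
    prior = prior_from_meta(summaries, weights.omega_p)

    fits = {}
    for i, arm in enumerate(arms):
        arm_cfg = McmcConfig(
            chains=mcmc.chains,
            iterations=mcmc.iterations,
            warmup=mcmc.warmup,
            rhat_threshold=mcmc.rhat_threshold,
            seed=replication_seed(cond, rep, 10 + i),
        )
        if arm == "pooled":
            fits[arm] = fit_pooled(focal, db, arm_cfg)
        elif arm == "npp":
            fits[arm] = fit_npp(focal, db, mcmc=arm_cfg)
        elif arm == "map":
            fits[arm] = fit_map(focal, summaries, arm_cfg)
        elif arm == "swip":
            fits[arm] = fit_swip(focal, prior, arm_cfg)
        else:
            raise ValueError(f"unknown arm {arm!r}")

    rows = []
    beta_F = np.asarray(true_params.beta_F)
    for arm, res in fits.items():
        for j in range(focal.p):
            rows.append(
                {
                    "rep": rep,
                    "arm": arm,
                    "coef": f"beta{j + 1}",
                    "estimate": res.coef_mean[j],
                    "se": res.coef_sd[j],
                    "shrinkage": shrinkage(beta_F[j], res.coef_mean[j]),
                    "max_rhat": res.max_rhat,
                    "omega": weights.omega_p[j],
                    "B_bar": gen.B_bar,
                    "tau2_hat": summaries[j].tau2,
                    "delta_tau2_hat": summaries[j].delta_tau2,
                }
            )
    meta_rhat = max(s.max_rhat for s in summaries)
    fit_rhat = max(res.max_rhat for res in fits.values())
    return pd.DataFrame(rows), fit_rhat, meta_rhat


def run_condition(
    cond: SimCondition,
    true_params: TrueParams = DEFAULT_TRUE_PARAMS,
    arms=ALL_ARMS,
    mcmc: McmcConfig = McmcConfig(),
    omega_config: OmegaConfig = OmegaConfig(),
) -> ConditionResult:
    """All replications of one condition; per-replication crashes are
    captured, logged and excluded from the aggregates."""
    if len(arms) == 0:
        raise ValueError("need at least one analysis arm")
    reps, failures = [], 0
    max_rhat = 0.0
    for rep in range(cond.n_reps):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df, fit_rhat, _ = _run_replication(
                    cond, true_params, arms, mcmc, omega_config, rep
                )
            reps.append(df)
            max_rhat = max(max_rhat, fit_rhat)
        except Exception:
            failures += 1
            logger.exception(
                "replication %d of condition (K=%d, dN=%d, dMu=%.2f, tau2=%.3f) failed",
                rep, cond.K, cond.delta_N, cond.delta_mu, cond.tau2,
            )
    if not reps:
        raise RuntimeError("all replications of the condition failed")
    repl = pd.concat(reps, ignore_index=True)

    summary = (
        repl.groupby(["arm", "coef"])
        .agg(
            mean_estimate=("estimate", "mean"),
            avg_se=("se", lambda s: float(np.sqrt(np.mean(np.square(s))))),
            mean_shrinkage=("shrinkage", "mean"),
        )
        .reset_index()
    )
    components = (
        repl[repl["arm"] == repl["arm"].iloc[0]]
        .groupby("coef")
        .agg(
            mean_omega=("omega", "mean"),
            mean_B_bar=("B_bar", "mean"),
            mean_tau2=("tau2_hat", "mean"),
            mean_delta_tau2=("delta_tau2_hat", "mean"),
        )
        .reset_index()
    )
    return ConditionResult(
        condition=cond,
        n_completed=int(repl["rep"].nunique()),
        n_failed=failures,
        max_rhat=max_rhat,
        summary=summary,
        components=components,
        replications=repl,
    )


def count_datasets(conditions) -> int:
    """Number of simulated datasets the design implies (one focal dataset
    plus its study database per replication)."""
    return int(sum(c.n_reps for c in conditions))


def grid_corner_conditions(
    n_reps: int = 5, base_seed: int = 0, moderator_r2: float = 0.1
) -> list:
    """Eight conditions spanning the corners of the design grid.

    The even-parity half fraction of the 2^4 corner cube over
    K in {3, 10}, delta_N in {-100, 100}, delta_mu in {0.25, 3} and
    tau2 in {0.025, 0.5}, so every factor appears at both extremes.
    """
    levels = {
        "K": (3, 10),
        "delta_N": (-100, 100),
        "delta_mu": (0.25, 3.0),
        "tau2": (0.025, 0.5),
    }
    conds = []
    idx = 0
    for iK in range(2):
        for iN in range(2):
            for iM in range(2):
                for iT in range(2):
                    if (iK + iN + iM + iT) % 2 != 0:
                        continue
                    seed = int(
                        np.random.SeedSequence([base_seed, 777, idx]).generate_state(1)[0]
                    ) % (2**31)
                    conds.append(
                        SimCondition(
                            K=levels["K"][iK],
                            delta_N=levels["delta_N"][iN],
                            delta_mu=levels["delta_mu"][iM],
                            tau2=levels["tau2"][iT],
                            moderator_r2=moderator_r2,
                            n_reps=n_reps,
                            seed=seed,
                        )
                    )
                    idx += 1
    return conds


def run_study(
    conditions,
    true_params: TrueParams = DEFAULT_TRUE_PARAMS,
    arms=ALL_ARMS,
    mcmc: McmcConfig = McmcConfig(),
    omega_config: OmegaConfig = OmegaConfig(),
    out_dir: str | Path | None = None,
) -> list:
    """Run every condition and optionally write the study tables."""
    results = []
    for i, cond in enumerate(conditions):
        logger.info("condition %d/%d", i + 1, len(conditions))
        results.append(run_condition(cond, true_params, arms, mcmc, omega_config))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tables(results, out)
    return results


def _condition_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.condition
        rows.append(
            {
                "K": c.K,
                "delta_N": c.delta_N,
                "delta_mu": c.delta_mu,
                "tau2": c.tau2,
                "total_het": total_heterogeneity(c.tau2, c.moderator_r2),
                "n_completed": r.n_completed,
                "n_failed": r.n_failed,
                "max_rhat": r.max_rhat,
                "mean_omega": r.mean_omega,
                "mean_B_bar": float(r.components["mean_B_bar"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _write_tables(results, out: Path) -> None:
    _condition_frame(results).to_csv(out / "conditions.csv", index=False)
    pd.concat(
        [r.replications.assign(condition=i) for i, r in enumerate(results)],
        ignore_index=True,
    ).to_csv(out / "replications.csv", index=False)
    pd.concat(
        [r.summary.assign(condition=i) for i, r in enumerate(results)],
        ignore_index=True,
    ).to_csv(out / "aggregate.csv", index=False)
    behavior_models(results).to_csv(out / "behavior_models.csv", index=False)


def behavior_models(results, shrinkage_arm: str = "swip") -> pd.DataFrame:
    """Linear models describing the similarity measure's behavior.

    Model "omega": per-condition mean omega regressed on the design's
    total heterogeneity tau2 + delta_tau2 and on delta_mu (both slopes
    expected negative).  Model "shrinkage": per-condition mean absolute
    shrinkage of ``shrinkage_arm`` regressed on mean omega (slope
    expected positive).
    """
    import statsmodels.api as sm

    if len(results) < 2:
        raise ValueError("behavior models need at least 2 conditions")
    df = _condition_frame(results)
    df["abs_shrinkage"] = [
        r.summary.loc[r.summary["arm"] == shrinkage_arm, "mean_shrinkage"].abs().mean()
        if (r.summary["arm"] == shrinkage_arm).any()
        else np.nan
        for r in results
    ]

    rows = []

    def _ols(yname, y, Xdf, model):
        keep = [c for c in Xdf.columns if Xdf[c].std() > 1e-12]
        if len(keep) < len(Xdf.columns):
            warnings.warn(f"{model}: dropped constant regressors", stacklevel=2)
        X = sm.add_constant(Xdf[keep]) if keep else pd.DataFrame(
            {"const": np.ones(len(Xdf))}
        )
        fit = sm.OLS(y, X).fit()
        for term in X.columns:
            rows.append(
                {
                    "model": model,
                    "term": term,
                    "coef": fit.params[term],
                    "se": fit.bse[term],
                    "pvalue": fit.pvalues[term],
                }
            )

    _ols("mean_omega", df["mean_omega"], df[["total_het", "delta_mu"]], "omega")
    if df["abs_shrinkage"].notna().all():
        _ols("abs_shrinkage", df["abs_shrinkage"], df[["mean_omega"]], "shrinkage")
    return pd.DataFrame(rows)
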