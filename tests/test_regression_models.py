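import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from swip.mcmc import McmcConfig
from swip.meta_analysis import HeterogeneitySummary
from swip.regression_models import (
    DIFFUSE_VAR,
    INTERCEPT_VAR,
    PosteriorSummary,
    PriorSpec,
    bridge_to_coefficient_scale,
    fit_map,
    fit_npp,
    fit_pooled,
    fit_swip,
)
from swip.simgen import RegressionDataset, SimCondition, StudyDatabase, TrueParams
from swip.simgen import generate_database, generate_focal


def _toy(n=50, p=1, beta=(0.5,), sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = X @ np.asarray(beta) + rng.normal(0, sigma, n)
    return RegressionDataset(y=y, X=X, study_id="toy")


def _conjugate_posterior(ds, prior_mean, prior_var, sigma=1.0):
    """Closed-form normal posterior with known sigma (independent oracle)."""
    Xa = np.column_stack([np.ones(ds.n), ds.X])
    P = Xa.T @ Xa / sigma**2 + np.diag(1.0 / np.asarray(prior_var))
    V = np.linalg.inv(P)
    m = V @ (Xa.T @ ds.y / sigma**2 + np.asarray(prior_mean) / np.asarray(prior_var))
    return m, np.sqrt(np.diag(V))


def _ols(ds):
    Xa = np.column_stack([np.ones(ds.n), ds.X])
    return np.linalg.lstsq(Xa, ds.y, rcond=None)[0]


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(mu_prior=[0.4], sd_prior=[0.0], omega=[0.5])
    with pytest.raises(ValueError):
        PriorSpec(mu_prior=[0.4], sd_prior=[0.1], omega=[1.5])
    with pytest.raises(ValueError):
        PriorSpec(mu_prior=[0.4, 0.1], sd_prior=[0.1], omega=[0.5])


def test_swip_power_prior_conjugate_oracle():
    """N(mu, v)^omega equals N(mu, v / omega): with sigma = 1 held fixed,
    the posterior matches the conjugate closed form with the inflated
    prior variance within Monte-Carlo error."""
    ds = _toy(n=50, seed=3)
    prior = PriorSpec(mu_prior=[0.4], sd_prior=[0.1], omega=[0.25])
    res = fit_swip(ds, prior, McmcConfig(seed=17), sigma_fixed=1.0)
    m, sd = _conjugate_posterior(
        ds, [0.0, 0.4], [INTERCEPT_VAR, 0.1**2 / 0.25], sigma=1.0
    )
    mcse = sd / np.sqrt(res.n_draws)
    assert np.all(np.abs(res.mean[:2] - m) < 2 * mcse)
    assert np.all(np.abs(res.sd[:2] - sd) < 0.01)


def test_swip_omega_one_equals_unweighted_informative():
    """Raising the prior to the power 1 leaves it unchanged: identical
    sampler inputs give bit-identical draws."""
    from swip.regression_models import _augment, _gibbs_linreg

    ds = _toy(n=60, seed=4)
    prior = PriorSpec(mu_prior=[0.4], sd_prior=[0.15], omega=[1.0])
    cfg = McmcConfig(seed=9, iterations=600, warmup=300)
    res = fit_swip(ds, prior, cfg)
    direct = _gibbs_linreg(
        ds.y, _augment(ds), np.array([0.0, 0.4]),
        np.array([INTERCEPT_VAR, 0.15**2]), cfg, arm="direct",
    )
    np.testing.assert_array_equal(res.draws["beta"], direct.draws["beta"])


def test_swip_zero_weight_flat_prior_limit(true_params):
    """All omega below the floor: posterior means sit at the focal OLS
    estimates within Monte-Carlo error."""
    ds = generate_focal(true_params, 8)
    prior = PriorSpec(
        mu_prior=[0.4, 0.0, 0.3], sd_prior=[0.05] * 3, omega=[0.0] * 3
    )
    res = fit_swip(ds, prior, McmcConfig(seed=21))
    np.testing.assert_allclose(res.coef_mean, _ols(ds)[1:], atol=0.02)


@pytest.mark.parametrize("w", [0.1, 0.4, 0.8])
def test_swip_posterior_mean_between_ols_and_prior(w):
    """Conjugate shrinkage: for any omega in (0, 1] the slope posterior
    mean lies between the focal estimate and the prior mean (fixed sigma)."""
    ds = _toy(n=200, beta=(0.5,), seed=5)
    prior_mean = -0.2
    prior = PriorSpec(mu_prior=[prior_mean], sd_prior=[0.05], omega=[w])
    res = fit_swip(ds, prior, McmcConfig(seed=31), sigma_fixed=1.0)
    ols_slope = _ols(ds)[1]
    lo, hi = sorted([ols_slope, prior_mean])
    assert lo - 0.01 <= res.mean[1] <= hi + 0.01


def test_swip_posterior_sd_decreases_with_omega():
    """More prior weight, more information: the slope posterior SD is
    non-increasing in omega."""
    ds = _toy(n=100, seed=6)
    sds = []
    for w in (0.05, 0.25, 0.5, 1.0):
        prior = PriorSpec(mu_prior=[0.3], sd_prior=[0.05], omega=[w])
        res = fit_swip(ds, prior, McmcConfig(seed=41), sigma_fixed=1.0)
        sds.append(res.sd[1])
    assert all(a >= b - 0.002 for a, b in zip(sds, sds[1:]))
    assert sds[0] > sds[-1]


def test_pooled_without_database_matches_focal_ols(true_params):
    ds = generate_focal(true_params, 9)
    res = fit_pooled(ds, None, McmcConfig(seed=51))
    np.testing.assert_allclose(res.coef_mean, _ols(ds)[1:], atol=0.02)
    assert res.converged


def test_pooled_more_data_smaller_se(true_params):
    """Pooling homogeneous studies shrinks the posterior SDs."""
    tp = TrueParams(beta_F=true_params.beta_F, mu_beta_k=true_params.beta_F)
    ds = generate_focal(tp, 10)
    cond = SimCondition(K=5, delta_N=0, delta_mu=0.0, tau2=1e-8, n_reps=1)
    db = generate_database(cond, tp, 11)
    alone = fit_pooled(ds, None, McmcConfig(seed=61))
    pooled = fit_pooled(ds, db, McmcConfig(seed=61))
    assert np.all(pooled.coef_sd < alone.coef_sd)


def test_pooled_weighted_least_squares_oracle():
    """Two-study pooling at fixed sigma matches the conjugate closed form
    on the stacked rows."""
    a, b = _toy(n=40, seed=12), _toy(n=30, beta=(0.3,), seed=13)
    db = StudyDatabase(studies=[b], moderators=np.zeros(1))
    res = fit_pooled(a, db, McmcConfig(seed=71), sigma_fixed=1.0)
    stacked = RegressionDataset(
        y=np.concatenate([a.y, b.y]), X=np.vstack([a.X, b.X])
    )
    m, sd = _conjugate_posterior(
        stacked, [0.0, 0.0], [INTERCEPT_VAR, DIFFUSE_VAR], sigma=1.0
    )
    assert np.all(np.abs(res.mean[:2] - m) < 3 * sd / np.sqrt(res.n_draws))


def _summary_for(mu_z, se_z, tau2):
    return HeterogeneitySummary(
        predictor_index=1, mu_z=mu_z, se_z=se_z, tau2=tau2,
        tau2_res=tau2, delta_tau2=0.0,
    )


def test_map_collapses_without_heterogeneity_or_robustification():
    """tau2 = 0 and robust weight 0: the MAP prior is exactly N(mu, se^2),
    so the fit coincides draw-for-draw with the plain informative prior."""
    ds = _toy(n=60, seed=14)
    s = _summary_for(mu_z=0.35, se_z=0.08, tau2=0.0)
    cfg = McmcConfig(seed=81, iterations=600, warmup=300)
    res_map = fit_map(ds, [s], cfg, robust_weight=0.0)
    r, se_r, _ = bridge_to_coefficient_scale(s)
    res_swip = fit_swip(
        ds, PriorSpec(mu_prior=[r], sd_prior=[se_r], omega=[1.0]), cfg
    )
    np.testing.assert_array_equal(
        res_map.draws["beta"], res_swip.draws["beta"]
    )


def test_map_fully_vague_mixture_matches_focal_fit(true_params):
    ds = generate_focal(true_params, 15)
    summaries = [_summary_for(0.4, 0.05, 0.01) for _ in range(3)]
    res = fit_map(ds, summaries, McmcConfig(seed=91), robust_weight=1.0)
    np.testing.assert_allclose(res.coef_mean, _ols(ds)[1:], atol=0.02)


def test_map_large_heterogeneity_vague_predictive(true_params):
    """With tau2 = 0.5 the predictive prior is so wide that the posterior
    stays at the focal-only estimates."""
    ds = generate_focal(true_params, 16)
    summaries = [_summary_for(0.4, 0.05, 0.5) for _ in range(3)]
    res = fit_map(ds, summaries, McmcConfig(seed=101), robust_weight=0.2)
    np.testing.assert_allclose(res.coef_mean, _ols(ds)[1:], atol=0.05)


def test_map_robust_weight_validation(true_params):
    ds = generate_focal(true_params, 17)
    with pytest.raises(ValueError):
        fit_map(ds, [_summary_for(0.4, 0.05, 0.1)] * 3, robust_weight=1.5)


# ---------------------------------------------------------------------------
# NPP


def _npp_toy(seed=18):
    rng = np.random.default_rng(seed)
    Xf = rng.standard_normal((40, 1))
    yf = 0.5 * Xf[:, 0] + rng.standard_normal(40)
    X0 = rng.standard_normal((60, 1))
    y0 = 0.35 * X0[:, 0] + rng.standard_normal(60)
    focal = RegressionDataset(y=yf, X=Xf, study_id="focal")
    db = StudyDatabase(
        studies=[RegressionDataset(y=y0, X=X0, study_id="hist")],
        moderators=np.zeros(1),
    )
    return focal, db


def _nig_conjugate_mean(X, y, V0_diag, a, b):
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    P = np.diag(1.0 / np.asarray(V0_diag)) + Xa.T @ Xa
    return np.linalg.solve(P, Xa.T @ y)


def test_npp_no_borrowing_equals_focal_conjugate():
    focal, db = _npp_toy()
    res = fit_npp(focal, db, a0_grid=np.array([0.0]), mcmc=McmcConfig(seed=111))
    m = _nig_conjugate_mean(focal.X, focal.y, [INTERCEPT_VAR, DIFFUSE_VAR], 0.01, 0.01)
    mcse = 3 * res.sd[:2] / np.sqrt(res.n_draws)
    assert np.all(np.abs(res.mean[:2] - m) < mcse)


def test_npp_full_borrowing_equals_pooled_conjugate():
    focal, db = _npp_toy()
    res = fit_npp(focal, db, a0_grid=np.array([1.0]), mcmc=McmcConfig(seed=121))
    X = np.vstack([focal.X, db.studies[0].X])
    y = np.concatenate([focal.y, db.studies[0].y])
    m = _nig_conjugate_mean(X, y, [INTERCEPT_VAR, DIFFUSE_VAR], 0.01, 0.01)
    mcse = 3 * res.sd[:2] / np.sqrt(res.n_draws)
    assert np.all(np.abs(res.mean[:2] - m) < mcse)


def test_npp_mixture_matches_quadrature_oracle():
    """Three-point a0 grid: the mixture weights and posterior mean agree
    with brute-force numerical integration of the joint posterior over
    (beta0, beta1, log sigma^2) for each a0 point."""
    focal, db = _npp_toy(seed=19)
    hist = db.studies[0]
    a0_grid = np.array([0.3, 0.6, 1.0])
    ig_a, ig_b = 3.0, 2.0
    res = fit_npp(
        focal, db, a0_grid=a0_grid, mcmc=McmcConfig(seed=131),
        ig_shape=ig_a, ig_scale=ig_b,
    )
    w_impl = res.draws["a0_weights"]
    mean_impl = w_impl @ res.draws["a0_component_means"]

    # --- independent oracle: dense tensor quadrature ---
    def suffstats(ds):
        Xa = np.column_stack([np.ones(ds.n), ds.X])
        return Xa.T @ Xa, Xa.T @ ds.y, float(ds.y @ ds.y), ds.n

    Gf, hf, yyf, nf = suffstats(focal)
    G0, h0, yy0, n0 = suffstats(hist)
    ols = np.linalg.solve(Gf + G0, hf + h0)
    b0g = np.linspace(ols[0] - 1.6, ols[0] + 1.6, 400)
    b1g = np.linspace(ols[1] - 1.6, ols[1] + 1.6, 400)
    ug = np.linspace(-2.5, 2.5, 120)
    B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")

    def ssr(G, h, yy):
        return (
            yy - 2 * (B0 * h[0] + B1 * h[1])
            + B0**2 * G[0, 0] + 2 * B0 * B1 * G[0, 1] + B1**2 * G[1, 1]
        )

    ssr_f, ssr_0 = ssr(Gf, hf, yyf), ssr(G0, h0, yy0)
    v_diag = np.array([INTERCEPT_VAR, DIFFUSE_VAR])
    prior_quad = B0**2 / v_diag[0] + B1**2 / v_diag[1]

    oracle_w = np.empty(3)
    oracle_mean = np.empty(3)
    for g, a0 in enumerate(a0_grid):
        lf_full, lf_prior, num_b1 = [], [], []
        for u in ug:
            s2 = np.exp(u)
            base = (
                -0.5 * (a0 * n0 + 2) * (u + np.log(2 * np.pi))
                - 0.5 * (a0 * ssr_0 + prior_quad) / s2
                - 0.5 * np.log(v_diag[0] * v_diag[1])
                + ig_a * np.log(ig_b) - gammaln(ig_a)
                - (ig_a + 1) * u - ig_b / s2 + u  # IG density + du jacobian
            )
            full = base - 0.5 * nf * (u + np.log(2 * np.pi)) - 0.5 * ssr_f / s2
            lf_prior.append(logsumexp(base))
            lf_full.append(logsumexp(full))
            num_b1.append(logsumexp(full, b=np.where(B1 > 0, B1, 1e-300)))
        log_zfull = logsumexp(lf_full)
        # E[b1] handled via positive/negative split to stay in log space
        neg = []
        for u in ug:
            s2 = np.exp(u)
            base = (
                -0.5 * (a0 * n0 + 2) * (u + np.log(2 * np.pi))
                - 0.5 * (a0 * ssr_0 + prior_quad) / s2
                - 0.5 * np.log(v_diag[0] * v_diag[1])
                + ig_a * np.log(ig_b) - gammaln(ig_a)
                - (ig_a + 1) * u - ig_b / s2 + u
            )
            full = base - 0.5 * nf * (u + np.log(2 * np.pi)) - 0.5 * ssr_f / s2
            neg.append(logsumexp(full, b=np.where(B1 < 0, -B1, 1e-300)))
        e_pos = np.exp(logsumexp(np.array(num_b1)) - log_zfull)
        e_neg = np.exp(logsumexp(np.array(neg)) - log_zfull)
        oracle_mean[g] = e_pos - e_neg
        oracle_w[g] = log_zfull - logsumexp(lf_prior)
    oracle_w = np.exp(oracle_w - oracle_w.max())
    oracle_w /= oracle_w.sum()

    np.testing.assert_allclose(w_impl, oracle_w, atol=1e-6)
    np.testing.assert_allclose(
        mean_impl[1], float(oracle_w @ oracle_mean), atol=1e-6
    )
    # the sampled posterior mean agrees within Monte-Carlo error
    assert abs(res.mean[1] - mean_impl[1]) < 4 * res.sd[1] / np.sqrt(res.n_draws)


def test_npp_singular_design_rejected():
    X = np.ones((10, 1))
    ds = RegressionDataset(y=np.arange(10.0), X=X)
    db = StudyDatabase(
        studies=[RegressionDataset(y=np.arange(8.0), X=np.ones((8, 1)))],
        moderators=np.zeros(1),
    )
    with pytest.raises(np.linalg.LinAlgError):
        fit_npp(ds, db, mcmc=McmcConfig(seed=141))


def test_all_arms_report_rhat_for_every_parameter(small_focal, small_db):
    from swip.meta_analysis import effect_sizes, mixed_effects_meta, records_for_predictor

    cfg = McmcConfig(seed=151, iterations=800, warmup=400)
    recs = effect_sizes(small_db)
    summaries = [
        mixed_effects_meta(records_for_predictor(recs, j + 1), small_db.moderators, cfg)
        for j in range(3)
    ]
    prior = PriorSpec(
        mu_prior=[0.4, 0.0, 0.3], sd_prior=[0.1] * 3, omega=[0.5] * 3
    )
    fits = [
        fit_swip(small_focal, prior, cfg),
        fit_pooled(small_focal, small_db, cfg),
        fit_map(small_focal, summaries, cfg),
        fit_npp(small_focal, small_db, mcmc=cfg),
    ]
    for res in fits:
        assert len(res.rhat) == len(res.params) == 5  # beta0..beta3, sigma
        assert np.all(np.isfinite(res.rhat))
        assert res.max_rhat == pytest.approx(np.max(res.rhat))
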