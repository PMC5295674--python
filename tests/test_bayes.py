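"""Bayesian modelling: VIF, multilevel screen, MCMC machinery, DIC,
posterior summaries and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from stuntgeo import bayes
from stuntgeo.spatial import distance_matrix_km


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        X = np.column_stack([np.tile([1, -1], n // 2),
                             np.repeat([1, -1], n // 2),
                             np.tile([1, 1, -1, -1], n // 4)])
        vif = bayes.compute_vif(X)
        np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=100)
        vif = bayes.compute_vif(np.column_stack([x, x, rng.normal(size=100)]))
        assert np.isinf(vif.iloc[0]) and np.isinf(vif.iloc[1])

    def test_correlated_pair_closed_form(self, rng):
        # rho = 0.9 -> VIF ~ 1/(1 - 0.81) ~ 5.26
        n = 50_000
        x = rng.standard_normal(n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        vif = bayes.compute_vif(np.column_stack([x, y]))
        assert vif.iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_more_columns_than_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            bayes.compute_vif(rng.normal(size=(3, 5)))


# ---------------------------------------------------------------------------
# Two-level random-intercept logistic screen
# ---------------------------------------------------------------------------

def _clustered_logit_data(rng, n=600, n_keb=6, n_vil=12, beta1=0.0, s_keb=0.0, s_vil=0.0):
    keb_of_vil = rng.integers(0, n_keb, n_vil)
    vil = rng.integers(0, n_vil, n)
    keb = keb_of_vil[vil]
    x = (rng.random(n) < 0.5).astype(float)
    u_k = rng.normal(0, np.sqrt(s_keb), n_keb) if s_keb else np.zeros(n_keb)
    u_v = rng.normal(0, np.sqrt(s_vil), n_vil) if s_vil else np.zeros(n_vil)
    eta = -0.3 + beta1 * x + u_k[keb] + u_v[vil]
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"stunted": y, "x": np.where(x == 1, "b", "a"),
                         "kebele_id": keb, "village_id": vil})


class TestUnivariableScreen:
    def test_reduces_to_plain_logistic_without_clustering(self, rng):
        df = _clustered_logit_data(rng, n=1200, beta1=0.6)
        res = bayes.univariable_screen(df, "x")
        X = sm.add_constant((df["x"] == "b").astype(float))
        glm = sm.GLM(df["stunted"], X, family=sm.families.Binomial()).fit()
        p_plain = glm.pvalues.iloc[1]
        # with zero cluster variance the Laplace fit should track the
        # ordinary Wald p-value closely
        assert res.p_values[0] == pytest.approx(p_plain, rel=0.2, abs=1e-4)
        assert res.estimates[0] == pytest.approx(glm.params.iloc[1], rel=0.1)

    def test_strong_effect_retained(self, rng):
        for s in range(5):
            df = _clustered_logit_data(np.random.default_rng(100 + s), n=2000,
                                       beta1=np.log(3.0), s_vil=0.2)
            assert bayes.univariable_screen(df, "x").retained

    def test_null_retention_rate_calibrated(self):
        """Under the null, retention at threshold 0.2 should run near 20%."""
        n_sims, retained = 200, 0
        for s in range(n_sims):
            df = _clustered_logit_data(np.random.default_rng(5000 + s), n=300,
                                       n_keb=4, n_vil=8)
            if bayes.univariable_screen(df, "x").retained:
                retained += 1
        rate = retained / n_sims
        se = np.sqrt(0.2 * 0.8 / n_sims)
        assert abs(rate - 0.2) < 3 * se

    def test_cluster_variance_recovered_when_present(self, rng):
        df = _clustered_logit_data(rng, n=4000, n_keb=8, n_vil=40, s_vil=1.0)
        res = bayes.univariable_screen(df, "x")
        assert res.fit.sigma2_village > 0.2

    def test_single_level_rejected(self, rng):
        df = _clustered_logit_data(rng, n=100)
        df["x"] = "a"
        with pytest.raises(ValueError):
            bayes.univariable_screen(df, "x")


# ---------------------------------------------------------------------------
# Likelihood and GP-prior correctness of the sampler
# ---------------------------------------------------------------------------

def _toy_spatial_model(rng, n=400, nv=8, sigma2=1.0, phi=0.3, beta=(-0.4, 0.7)):
    lon = 38.0 + rng.random(nv) * 0.2
    lat = 8.0 + rng.random(nv) * 0.2
    D = distance_matrix_km(lon, lat)
    vidx = rng.integers(0, nv, n)
    x = (rng.random(n) < 0.5).astype(float)
    L = np.linalg.cholesky(sigma2 * np.exp(-phi * D) + 1e-9 * np.eye(nv))
    S = L @ rng.standard_normal(nv)
    eta = beta[0] + beta[1] * x + S[vidx]
    y = (rng.random(n) < expit(eta)).astype(float)
    model = bayes.GeoLogisticModel(y=y, X=x[:, None], names=["x"], spatial=True,
                                   village_index=vidx, distances_km=D)
    return model, S


class TestLikelihood:
    def test_deviance_matches_per_record_bernoulli_sum(self, rng):
        model, S = _toy_spatial_model(rng)
        beta = np.array([-0.2, 0.5])
        dev = bayes.model_deviance(model, beta, S)
        # brute force: sum log p(y_i) record by record
        acc = 0.0
        for i in range(len(model.y)):
            eta = beta[0] + beta[1] * model.X[i, 0] + S[model.village_index[i]]
            p = 1 / (1 + np.exp(-eta))
            acc += np.log(p) if model.y[i] == 1 else np.log(1 - p)
        assert dev == pytest.approx(-2 * acc, abs=1e-10)


class TestSamplerTargetsPrior:
    def test_spatial_draws_follow_gp_prior_without_data(self, rng):
        """With no observations the S-updates must target the GP prior:
        the empirical covariance of sampled S matches sigma2*exp(-phi*d)."""
        nv = 5
        lon = 38.0 + np.arange(nv) * 0.05
        lat = np.full(nv, 8.0)
        D = distance_matrix_km(lon, lat)
        phi0 = 0.25
        # pin sigma2 ~ 1 (tight IG) and phi ~ phi0 (degenerate bounds)
        priors = bayes.Priors(sigma2_shape=1e6, sigma2_rate=1e6,
                              phi_bounds=(phi0, phi0 * (1 + 1e-9)))
        model = bayes.GeoLogisticModel(
            y=np.empty(0), X=np.empty((0, 1)), names=["x"], spatial=True,
            village_index=np.empty(0, int), distances_km=D, priors=priors)
        cfg = bayes.MCMCConfig(burn_in=500, kept=8000, thin=1, n_chains=1, seed=10)
        draws = bayes.run_mcmc(model, cfg)
        S = draws.pooled("S")
        target = 1.0 * np.exp(-phi0 * D)
        emp = np.cov(S.T)
        assert np.abs(emp - target).max() < 0.15  # generous MC tolerance

    def test_nonspatial_equals_spatial_with_zero_variance(self, rng):
        """Forcing sigma2 to ~0 must reproduce the fixed-effects posterior."""
        model, _ = _toy_spatial_model(rng, n=800, sigma2=0.0)
        flat = bayes.GeoLogisticModel(y=model.y, X=model.X, names=model.names,
                                      spatial=False)
        pinned = bayes.Priors(sigma2_shape=1e8, sigma2_rate=1e0)  # mean ~ 1e-8
        near_zero = bayes.GeoLogisticModel(
            y=model.y, X=model.X, names=model.names, spatial=True,
            village_index=model.village_index, distances_km=model.distances_km,
            priors=pinned)
        cfg = bayes.MCMCConfig(burn_in=800, kept=4000, thin=2, n_chains=1, seed=21)
        b_flat = bayes.run_mcmc(flat, cfg).pooled("beta").mean(axis=0)
        b_zero = bayes.run_mcmc(near_zero, cfg).pooled("beta").mean(axis=0)
        np.testing.assert_allclose(b_flat, b_zero, atol=0.08)


class TestMcmcContracts:
    def test_reproducible_for_fixed_seed(self, rng):
        model, _ = _toy_spatial_model(rng, n=200)
        cfg = bayes.MCMCConfig(burn_in=100, kept=400, thin=2, n_chains=2, seed=3)
        a = bayes.run_mcmc(model, cfg)
        b = bayes.run_mcmc(model, cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.S, b.S)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            bayes.MCMCConfig(burn_in=0, kept=100, thin=1)
        with pytest.raises(ValueError):
            bayes.MCMCConfig(burn_in=10, kept=50, thin=1)  # kept/thin < 100

    def test_spatial_model_requires_geometry(self, rng):
        with pytest.raises(ValueError):
            bayes.GeoLogisticModel(y=np.zeros(5), X=np.zeros((5, 1)), names=["x"],
                                   spatial=True)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

class TestDic:
    def test_degenerate_posterior_has_zero_pd(self, rng):
        model, S = _toy_spatial_model(rng, n=100)
        beta = np.array([0.1, -0.2])
        draws = bayes.PosteriorDraws(
            beta=np.tile(beta, (1, 600, 1)), names=["intercept", "x"],
            deviance=np.full((1, 600), bayes.model_deviance(model, beta, S)),
            S=np.tile(S, (1, 600, 1)),
            sigma2=np.ones((1, 600)), phi=np.full((1, 600), 0.3))
        dic = bayes.compute_dic(draws, model)
        assert dic.p_d == pytest.approx(0.0, abs=1e-9)
        assert dic.dic == pytest.approx(dic.d_hat, abs=1e-9)

    def test_conjugate_normal_mean_closed_form(self, rng):
        """Normal-mean model with known variance: pD has the exact closed
        form n*Var(theta draws)/sigma^2, so DIC from deviance draws must
        match the analytic assembly to 1e-6."""
        n, s2 = 30, 2.0
        y = rng.normal(1.0, np.sqrt(s2), n)
        # conjugate posterior theta | y ~ N(post_mean, post_var) (flat prior)
        post_mean, post_var = y.mean(), s2 / n
        theta = rng.normal(post_mean, np.sqrt(post_var), 5000)
        const = n * np.log(2 * np.pi * s2)
        dev = const + ((y[None, :] - theta[:, None]) ** 2).sum(axis=1) / s2
        dev_at_mean = const + ((y - theta.mean()) ** 2).sum() / s2
        res = bayes.dic_from_deviance(dev, dev_at_mean)
        p_d_analytic = n * theta.var() / s2
        assert res.p_d == pytest.approx(p_d_analytic, abs=1e-6)
        assert res.dic == pytest.approx(res.d_bar + p_d_analytic, abs=1e-6)

    def test_too_few_draws_rejected(self, rng):
        model, S = _toy_spatial_model(rng, n=50)
        draws = bayes.PosteriorDraws(beta=np.zeros((1, 100, 2)), names=["a", "b"],
                                     deviance=np.zeros((1, 100)))
        with pytest.raises(ValueError):
            bayes.compute_dic(draws, model)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_degenerate_draws(self):
        c = 0.37
        draws = bayes.PosteriorDraws(beta=np.full((1, 500, 2), c),
                                     names=["intercept", "x"],
                                     deviance=np.zeros((1, 500)))
        s = bayes.summarize_posterior(draws)
        row = s.loc["x"]
        assert row["mean"] == pytest.approx(c, rel=1e-12)
        assert row["median"] == pytest.approx(c, rel=1e-12)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert row["bci_2.5"] == pytest.approx(row["bci_97.5"], rel=1e-12)

    def test_or_interval_is_exp_of_coefficient_interval(self, rng):
        b = rng.normal(0.3, 0.2, size=(1, 2000, 2))
        draws = bayes.PosteriorDraws(beta=b, names=["intercept", "x"],
                                     deviance=np.zeros((1, 2000)))
        s = bayes.summarize_posterior(draws)
        row = s.loc["x"]
        assert row["or_2.5"] == pytest.approx(np.exp(row["bci_2.5"]), rel=1e-12)
        assert row["or_97.5"] == pytest.approx(np.exp(row["bci_97.5"]), rel=1e-12)
        assert row["bci_2.5"] <= row["median"] <= row["bci_97.5"]


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

class TestDiagnostics:
    def test_iid_chain_passes_geweke(self):
        flagged = 0
        for s in range(40):
            x = np.random.default_rng(s).standard_normal(2000)
            if abs(bayes.geweke_z(x)) >= 2:
                flagged += 1
        assert flagged <= 4  # >= 90% of well-mixed chains pass

    def test_trending_chain_fails_geweke(self):
        x = np.linspace(0, 5, 2000) + np.random.default_rng(0).standard_normal(2000) * 0.1
        assert abs(bayes.geweke_z(x)) > 4

    def test_iid_ess_near_n(self):
        x = np.random.default_rng(1).standard_normal(5000)
        assert bayes.effective_sample_size(x) == pytest.approx(5000, rel=0.15)

    def test_ar1_ess_closed_form(self):
        rho, n = 0.9, 40_000
        rng_ = np.random.default_rng(2)
        x = np.empty(n)
        x[0] = rng_.standard_normal()
        eps = rng_.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert bayes.effective_sample_size(x) == pytest.approx(expected, rel=0.30)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            bayes.geweke_z(np.arange(10.0))

    def test_diagnostics_table(self, rng):
        model, _ = _toy_spatial_model(rng, n=150)
        cfg = bayes.MCMCConfig(burn_in=200, kept=600, thin=2, n_chains=2, seed=8)
        draws = bayes.run_mcmc(model, cfg)
        diag = bayes.convergence_diagnostics(draws)
        assert {"geweke_z", "ess"} <= set(diag.columns)
        assert (diag["ess"] > 1).all()
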