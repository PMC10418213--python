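"""REML, Haseman-Elston, marginal GWAS and LD score regression."""

import numpy as np
import pandas as pd
import pytest

from admixherit import (
    build_genotype_grm,
    expected_marginal_effects,
    gwas_marginal,
    he_regression,
    ld_scores,
    ldsc_fit,
    principal_components,
    reml,
)
from admixherit.estimators import RemlWorkspace, SummaryStats, _he_slope


def _simulate_unstructured(n, m, h2, seed):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.9, size=m)
    X = rng.binomial(2, f, size=(n, m)).astype(float)
    u = rng.normal(0, 1, size=m)
    Z = (X - 2 * f) / np.sqrt(2 * f * (1 - f))
    g = Z @ u / np.sqrt(m)
    vg = np.var(g)
    e = rng.normal(0, np.sqrt(vg * (1 - h2) / h2), size=n)
    return X, g + e, vg


class TestREML:
    def test_recovers_heritability_without_structure(self):
        ests, truths = [], []
        for r in range(5):
            X, y, vg = _simulate_unstructured(800, 200, 0.8, seed=100 + r)
            K = build_genotype_grm(X, scaling="standard")
            est = reml(y, K)
            ests.append(est.h2)
            truths.append(0.8)
            assert est.converged
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 0.8) <= max(3 * se, 0.05)

    def test_identity_grm_is_unidentifiable(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        est = reml(y, np.eye(200))
        assert not est.converged

    def test_pure_noise_unconstrained_centers_at_zero(self):
        rng = np.random.default_rng(2)
        X, _, _ = _simulate_unstructured(400, 100, 0.8, seed=3)
        K = build_genotype_grm(X, scaling="standard")
        ws = RemlWorkspace(K)
        ests = np.array([ws.fit(rng.normal(size=400)).sigma_g2 for _ in range(20)])
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean()) <= 3 * se + 1e-3
        assert (ests < 0).any()  # negative estimates must be reachable

    def test_constrained_fit_never_negative(self):
        rng = np.random.default_rng(4)
        X, _, _ = _simulate_unstructured(300, 80, 0.8, seed=5)
        K = build_genotype_grm(X, scaling="standard")
        ws = RemlWorkspace(K)
        for _ in range(10):
            est = ws.fit(rng.normal(size=300), constrain=True)
            assert est.sigma_g2 >= 0
            assert est.constrained

    def test_workspace_matches_one_shot_fit(self):
        X, y, _ = _simulate_unstructured(300, 80, 0.8, seed=6)
        K = build_genotype_grm(X, scaling="standard")
        a = reml(y, K)
        b = RemlWorkspace(K).fit(y)
        assert a.sigma_g2 == pytest.approx(b.sigma_g2, rel=1e-12)

    def test_covariate_projection_removes_fixed_effect(self):
        rng = np.random.default_rng(7)
        X, y, _ = _simulate_unstructured(400, 100, 0.8, seed=8)
        c = rng.normal(size=400)
        K = build_genotype_grm(X, scaling="standard")
        base = reml(y, K)
        shifted = reml(y + 10.0 * c, K, covariates=c)
        assert shifted.sigma_g2 == pytest.approx(base.sigma_g2, rel=0.05)
        assert shifted.adjusted


class TestHasemanElston:
    def test_agrees_with_reml_without_structure(self):
        diffs = []
        for r in range(5):
            X, y, _ = _simulate_unstructured(600, 150, 0.8, seed=200 + r)
            K = build_genotype_grm(X, scaling="standard")
            he = he_regression(y, K)
            rm = reml(y, K)
            diffs.append(he.sigma_g2 - rm.sigma_g2)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) <= max(3 * se, 0.05)

    def test_jackknife_se_is_reported(self):
        X, y, _ = _simulate_unstructured(300, 80, 0.8, seed=9)
        K = build_genotype_grm(X, scaling="standard")
        est = he_regression(y, K)
        assert np.isfinite(est.se_sigma_g2) and est.se_sigma_g2 > 0

    def test_constant_grm_rejected(self):
        with pytest.raises(ValueError):
            he_regression(np.random.default_rng(0).normal(size=100), np.ones((100, 100)))

    def test_covariate_adjustment_projects_grm_too(self):
        # adding a strong covariate-aligned confound must not leak into
        # the adjusted slope
        rng = np.random.default_rng(10)
        X, y, _ = _simulate_unstructured(400, 100, 0.8, seed=11)
        c = rng.normal(size=400)
        K = build_genotype_grm(X, scaling="standard")
        adj_clean = he_regression(y, K, covariates=c)
        adj_conf = he_regression(y + 5 * c, K, covariates=c)
        assert adj_conf.sigma_g2 == pytest.approx(adj_clean.sigma_g2, abs=1e-8)


class TestMarginalGWAS:
    def test_matches_reference_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = rng.binomial(2, 0.4, size=(120, 5)).astype(float)
        c = rng.normal(size=120)
        y = rng.normal(size=120) + X[:, 0] * 0.5 + c
        stats = gwas_marginal(y, X, covariates=c)
        for j in range(5):
            D = sm.add_constant(np.column_stack([X[:, j], c]))
            fit = sm.OLS(y, D).fit()
            assert stats.beta[j] == pytest.approx(fit.params[1], rel=1e-10)
            assert stats.table["se"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-10)

    def test_null_trait_chi2_mean_is_one(self):
        rng = np.random.default_rng(13)
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(500, 300)).astype(float)
        y = rng.normal(size=500)
        stats = gwas_marginal(y, X)
        assert stats.chi2.mean() == pytest.approx(1.0, abs=0.15)

    def test_monomorphic_variants_flagged(self):
        rng = np.random.default_rng(14)
        X = rng.binomial(2, 0.5, size=(100, 3)).astype(float)
        X[:, 1] = 2.0
        stats = gwas_marginal(rng.normal(size=100), X)
        assert bool(stats.table["flagged"].iloc[1])
        assert np.isnan(stats.beta[1])
        assert not stats.table["flagged"].iloc[0]

    def test_perfect_fit_flagged(self):
        X = np.random.default_rng(15).binomial(2, 0.5, size=(50, 1)).astype(float)
        y = 2.0 * X[:, 0]
        stats = gwas_marginal(y, X)
        assert bool(stats.table["flagged"].iloc[0])


class TestExpectedMarginalEffects:
    def test_identity_ld_returns_causal_effects(self):
        beta = np.array([0.1, -0.2, 0.0])
        np.testing.assert_allclose(
            expected_marginal_effects(beta, np.eye(3)), beta
        )

    def test_tagging_hand_case(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        beta = np.array([1.0, 0.0])
        np.testing.assert_allclose(expected_marginal_effects(beta, R), [1.0, 0.5])

    def test_calibration_in_simulation(self, hi_trajectory, arch_divergent):
        # marginal effects on a noiseless trait should scatter around R beta_u
        coh = hi_trajectory[1]
        X = coh.X.astype(float)
        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / sd
        R = Z.T @ Z / coh.n
        u = arch_divergent.beta * sd  # effects on the standardized scale
        g = X @ arch_divergent.beta
        stats = gwas_marginal(g, Z)
        pred = expected_marginal_effects(u, R)
        slope = float(pred @ stats.beta / (pred @ pred))
        assert slope == pytest.approx(1.0, abs=0.1)


class TestLDScores:
    def test_single_variant_scores_one(self):
        X = np.random.default_rng(16).binomial(2, 0.5, size=(200, 1)).astype(float)
        assert ld_scores(X)[0] == pytest.approx(1.0)

    def test_unlinked_scores_near_noise_floor(self, unstructured_genotypes):
        n, m = unstructured_genotypes.shape
        ell = ld_scores(unstructured_genotypes)
        # E[l] ~ 1 + (m-1)/n for independent variants
        assert ell.mean() == pytest.approx(1.0 + (m - 1) / n, abs=0.05)

    def test_admixture_ld_raises_scores_and_projection_collapses_them(
        self, hi_trajectory
    ):
        coh = hi_trajectory[1]
        raw = ld_scores(coh.X)
        adj = ld_scores(coh.X, pcs_to_project=1)
        assert raw.mean() > adj.mean() + 0.2
        n, m = coh.X.shape
        assert adj.mean() < 1.0 + (m - 1) / n + 0.2

    def test_monomorphic_rejected(self):
        X = np.ones((50, 2))
        with pytest.raises(ValueError):
            ld_scores(X)


def _stats_from_chi2(chi2, n):
    m = chi2.size
    tab = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "beta": np.zeros(m),
            "se": np.ones(m),
            "chi2": chi2,
            "freq": np.full(m, 0.5),
            "flagged": np.zeros(m, dtype=bool),
        }
    )
    return SummaryStats(table=tab, n=n, n_covariates=0)


class TestLDSC:
    def test_recovers_slope_from_exact_expectations(self, hi_trajectory):
        # E[chi2_k] = (n sigma_u^2 / m) l_k + 1 exactly under the sample LD
        coh = hi_trajectory[1]
        n, m = coh.X.shape
        ell = ld_scores(coh.X)
        sigma_u2 = 0.8
        chi2 = n * sigma_u2 / m * ell + 1.0
        fit = ldsc_fit(_stats_from_chi2(chi2, n), ell, m=m)
        assert fit.slope == pytest.approx(n * sigma_u2 / m, rel=1e-10)
        assert fit.intercept == pytest.approx(1.0, rel=1e-10)
        assert fit.vg_hat == pytest.approx(sigma_u2, rel=1e-10)

    def test_monte_carlo_chi2_matches_slope(self, hi_trajectory):
        # chi2 = n (R u)^2 + 1 averaged over effect draws
        rng = np.random.default_rng(17)
        coh = hi_trajectory[1]
        X = coh.X.astype(float)
        n, m = X.shape
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        R = Z.T @ Z / n
        sigma_u2 = 0.5
        acc = np.zeros(m)
        reps = 800
        for _ in range(reps):
            u = rng.normal(0, np.sqrt(sigma_u2 / m), size=m)
            acc += n * (R @ u) ** 2 + 1.0
        ell = ld_scores(X)
        fit = ldsc_fit(_stats_from_chi2(acc / reps, n), ell, m=m)
        assert fit.slope == pytest.approx(n * sigma_u2 / m, rel=0.1)

    def test_weighting_options(self, hi_trajectory):
        coh = hi_trajectory[1]
        n, m = coh.X.shape
        ell = ld_scores(coh.X)
        chi2 = 2.0 * ell + 1.0
        st = _stats_from_chi2(chi2, n)
        a = ldsc_fit(st, ell, m=m, weights="ols")
        b = ldsc_fit(st, ell, m=m, weights="reciprocal_ell")
        # exact linear relation: both weightings recover it
        assert a.slope == pytest.approx(2.0, rel=1e-8)
        assert b.slope == pytest.approx(2.0, rel=1e-8)
        with pytest.raises(ValueError):
            ldsc_fit(st, ell, m=m, weights="magic")

    def test_flagged_variants_are_dropped(self, hi_trajectory):
        coh = hi_trajectory[1]
        n, m = coh.X.shape
        ell = ld_scores(coh.X)
        chi2 = 2.0 * ell + 1.0
        chi2[0] = np.nan
        fit = ldsc_fit(_stats_from_chi2(chi2, n), ell, m=m)
        assert fit.slope == pytest.approx(2.0, rel=1e-8)
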