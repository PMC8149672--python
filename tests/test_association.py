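"""Score tests, burden/SKAT, saddlepoint tail, and the Cauchy combination."""

import numpy as np
import pytest
from scipy import stats

from kscreen import (
    burden_test,
    cauchy_combine,
    fit_null_model,
    saddlepoint_pvalue,
    single_variant_score_test,
    skat_test,
    ultra_rare_burden,
    window_pvalue,
)
from kscreen.association import ScoreCache, _mixture_chi2_sf
from kscreen.panel import Window, categorize_variants

from conftest import make_panel


def perm_pvalue(null_Y, X, g, stat_fn, n_perm, rng):
    """Two-sided permutation p-value of a score-type statistic."""
    obs = abs(stat_fn(null_Y, g))
    hits = 0
    for _ in range(n_perm):
        hits += abs(stat_fn(rng.permutation(null_Y), g)) >= obs
    return (1 + hits) / (1 + n_perm)


class TestNullModel:
    def test_gaussian_intercept_only(self, rng):
        Y = rng.standard_normal(50)
        null = fit_null_model(Y)
        np.testing.assert_allclose(null.mu, Y.mean())

    def test_binomial_intercept_only_gives_prevalence(self, rng):
        Y = (rng.uniform(size=400) < 0.2).astype(float)
        null = fit_null_model(Y, family="binomial")
        np.testing.assert_allclose(null.mu, Y.mean(), atol=1e-8)

    def test_gaussian_coefficients_match_normal_equations(self, rng):
        X = rng.standard_normal((100, 2))
        Y = rng.standard_normal(100)
        null = fit_null_model(Y, X)
        Xi = np.column_stack([np.ones(100), X])
        ref = np.linalg.solve(Xi.T @ Xi, Xi.T @ Y)
        np.testing.assert_allclose(null.mu, Xi @ ref, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.standard_normal((200, 3))
        null = fit_null_model(rng.standard_normal(200), X)
        np.testing.assert_allclose(null.X.T @ null.resid, 0.0, atol=1e-8)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            fit_null_model(np.ones(20))


class TestSingleVariant:
    def test_null_pvalues_uniform(self, rng):
        n = 400
        ps = []
        for _ in range(400):
            null = fit_null_model(rng.standard_normal(n))
            g = rng.binomial(2, 0.2, n).astype(float)
            ps.append(single_variant_score_test(null, g))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_genotype_equal_to_covariate_fully_explained(self, rng):
        g = rng.binomial(2, 0.3, 150).astype(float)
        Y = rng.standard_normal(150)
        null = fit_null_model(Y, g[:, None])
        assert single_variant_score_test(null, g) > 0.99

    def test_matches_two_by_two_chisquare(self, rng):
        # balanced binomial, binary genotype, no covariates: the score test
        # collapses to the classical 2x2 chi-square independence test
        n = 600
        Y = (rng.uniform(size=n) < 0.5).astype(float)
        g = (rng.uniform(size=n) < 0.3).astype(float)
        null = fit_null_model(Y, family="binomial")
        p_score = single_variant_score_test(null, g)
        tab = np.array([
            [np.sum((Y == 0) & (g == 0)), np.sum((Y == 0) & (g == 1))],
            [np.sum((Y == 1) & (g == 0)), np.sum((Y == 1) & (g == 1))],
        ])
        chi2 = stats.chi2_contingency(tab, correction=False).statistic
        assert p_score == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-6)


class TestSaddlepoint:
    def test_zero_score_gives_one(self, rng):
        Y = (rng.uniform(size=200) < 0.5).astype(float)
        null = fit_null_model(Y, family="binomial")
        g = rng.binomial(2, 0.3, 200).astype(float)
        ga = null.adjust(g[:, None])[:, 0]
        assert saddlepoint_pvalue(0.0, ga, null) == 1.0

    def test_balanced_design_close_to_normal(self, rng):
        n = 2000
        Y = (rng.uniform(size=n) < 0.5).astype(float)
        null = fit_null_model(Y, family="binomial")
        g = rng.binomial(2, 0.3, n).astype(float)
        ga = null.adjust(g[:, None])[:, 0]
        u = float(ga @ null.resid)
        v = float((ga * null.weights) @ ga)
        p_norm = 2 * stats.norm.sf(abs(u) / np.sqrt(v))
        p_spa = saddlepoint_pvalue(u, ga, null)
        assert p_spa == pytest.approx(p_norm, rel=0.15)

    def test_unbalanced_rare_variant_matches_permutations(self, rng):
        # 1:49 case-control imbalance with a rare variant: the normal tail
        # is badly anti-conservative, the saddlepoint tail is not
        n = 2500
        Y = np.zeros(n)
        Y[:50] = 1.0
        rng.shuffle(Y)
        g = np.zeros(n)
        g[rng.choice(n, 40, replace=False)] = 1.0
        null = fit_null_model(Y, family="binomial")
        ga = null.adjust(g[:, None])[:, 0]
        u = float(ga @ null.resid)
        p_spa = saddlepoint_pvalue(u, ga, null)
        obs = abs(u)
        hits = 0
        n_perm = 20000
        for _ in range(n_perm):
            hits += abs(ga @ rng.permutation(Y) - ga @ null.mu) >= obs
        p_perm = (1 + hits) / (1 + n_perm)
        assert 0.5 < p_spa / p_perm < 2.0


class TestBurden:
    def test_single_variant_reduction(self, rng):
        Y = rng.standard_normal(300)
        null = fit_null_model(Y)
        g = rng.binomial(2, 0.2, 300).astype(float)
        assert burden_test(null, g[:, None], np.ones(1)) == pytest.approx(
            single_variant_score_test(null, g)
        )

    def test_zero_weights_error(self, rng):
        null = fit_null_model(rng.standard_normal(100))
        G = rng.binomial(2, 0.2, (100, 3)).astype(float)
        with pytest.raises(ValueError):
            burden_test(null, G, np.zeros(3))

    def test_matches_permutation_oracle(self, rng):
        n = 120
        Y = rng.standard_normal(n)
        G = rng.binomial(2, 0.25, (n, 3)).astype(float)
        w = np.array([0.5, 1.0, 2.0])
        null = fit_null_model(Y)
        p = burden_test(null, G, w)
        b = G @ w

        def stat(y, g):
            return g @ (y - y.mean())

        p_perm = perm_pvalue(Y, None, b, stat, 20000, rng)
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / 20000) + 0.01)


class TestSkat:
    def test_single_variant_reduction(self, rng):
        Y = rng.standard_normal(400)
        null = fit_null_model(Y)
        g = rng.binomial(2, 0.3, 400).astype(float)
        p_skat = skat_test(null, g[:, None], np.ones(1))
        p_sv = single_variant_score_test(null, g)
        assert p_skat == pytest.approx(p_sv, rel=1e-6)

    def test_null_pvalues_uniform(self, rng):
        n = 300
        ps = []
        for _ in range(400):
            null = fit_null_model(rng.standard_normal(n))
            G = rng.binomial(2, 0.1, (n, 5)).astype(float)
            ps.append(skat_test(null, G))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tail_matches_mixture_sampling_oracle(self, rng):
        # the saddlepoint inversion is essentially exact in the tail and
        # accurate to a few percent relative in the bulk
        lam = np.array([3.0, 1.5, 0.7, 0.2, 0.05])
        draws = (lam * rng.chisquare(1, (100000, 5))).sum(axis=1)
        for q in (5.0, 12.0, 20.0):
            p_emp = (draws > q).mean()
            se = np.sqrt(p_emp * (1 - p_emp) / draws.size)
            tol = 4 * se + 0.03 * p_emp
            assert _mixture_chi2_sf(q, lam) == pytest.approx(p_emp, abs=tol)


class TestUltraRare:
    def test_single_singleton_reduction(self, rng):
        n = 500
        Y = rng.standard_normal(n)
        null = fit_null_model(Y)
        g = np.zeros(n)
        g[7] = 1.0
        assert ultra_rare_burden(null, g[:, None]) == pytest.approx(
            single_variant_score_test(null, g)
        )

    def test_aggregation_beats_individual_singletons(self, rng):
        # inject the same effect on carriers of 10 singletons: the pooled
        # burden should usually beat every per-singleton test
        n = 400
        wins = 0
        reps = 60
        for _ in range(reps):
            G = np.zeros((n, 10))
            carriers = rng.choice(n, 10, replace=False)
            G[carriers, np.arange(10)] = 1.0
            Y = rng.standard_normal(n) + G.sum(axis=1) * 1.5
            null = fit_null_model(Y)
            p_burden = ultra_rare_burden(null, G)
            p_each = [single_variant_score_test(null, G[:, j]) for j in range(10)]
            wins += p_burden < min(p_each)
        assert wins / reps >= 0.8


class TestCauchyCombine:
    def test_all_half_gives_half(self):
        assert cauchy_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_input_identity(self):
        for p in (1e-8, 0.03, 0.4, 0.97):
            assert cauchy_combine([p]) == pytest.approx(p, rel=1e-6)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])

    def test_tiny_pvalue_asymptote_finite(self):
        p = cauchy_combine([1e-310, 0.5])
        assert 0 < p < 1e-300 * 1e10  # dominated by the tiny component

    def test_null_uniformity(self, rng):
        ps = [cauchy_combine(rng.uniform(size=5)) for _ in range(2000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWindowEnsemble:
    def _panel_all_categories(self, rng, n=2000):
        cols, mafs = [], [0.2, 0.3, 0.03, 0.005, 0.008]
        for f in mafs:
            cols.append(rng.binomial(2, f, n).astype(float))
        ultra = np.zeros(n)
        ultra[rng.choice(n, 3, replace=False)] = 1.0
        cols.append(ultra)
        return make_panel(np.column_stack(cols))

    def test_component_count_by_construction(self, rng):
        # common+lowfreq burden/skat (2) + rare burden/skat (2) + ultra (1)
        # + one single-variant test per variant
        panel = self._panel_all_categories(rng)
        cats = categorize_variants(panel)
        assert {"common", "low_frequency", "rare", "ultra_rare"} <= set(cats)
        null = fit_null_model(rng.standard_normal(panel.n))
        window = Window("chr1", 1, 1000, 1000, tuple(range(panel.p)))

        recorded = []
        import kscreen.association as assoc

        orig = assoc.cauchy_combine

        def spy(pvals, weights=None):
            recorded.append(len(pvals))
            return orig(pvals, weights)

        assoc.cauchy_combine, cc = spy, assoc.cauchy_combine
        try:
            window_pvalue(null, panel.dosages, window, cats, panel.maf)
        finally:
            assoc.cauchy_combine = cc
        assert recorded == [2 + 2 + 1 + panel.p]

    def test_annotation_weights_add_components(self, rng):
        panel = self._panel_all_categories(rng)
        cats = categorize_variants(panel)
        null = fit_null_model(rng.standard_normal(panel.n))
        window = Window("chr1", 1, 1000, 1000, tuple(range(panel.p)))
        ann = rng.uniform(size=(panel.p, 2))
        p_no = window_pvalue(null, panel.dosages, window, cats, panel.maf)
        p_ann = window_pvalue(
            null, panel.dosages, window, cats, panel.maf, annotations=ann
        )
        assert p_no != p_ann  # two extra burden/skat pairs entered

    def test_identical_input_identical_pvalue(self, rng):
        panel = self._panel_all_categories(rng)
        cats = categorize_variants(panel)
        null = fit_null_model(rng.standard_normal(panel.n))
        window = Window("chr1", 1, 1000, 1000, tuple(range(panel.p)))
        p1 = window_pvalue(null, panel.dosages, window, cats, panel.maf)
        p2 = window_pvalue(null, panel.dosages.copy(), window, cats, panel.maf)
        assert p1 == p2

    def test_cache_agrees_with_standalone_tests(self, rng):
        """The fast cached path must agree with the standalone test functions."""
        panel = self._panel_all_categories(rng)
        null = fit_null_model(rng.standard_normal(panel.n))
        cache = ScoreCache(null, panel.dosages)
        for j in range(panel.p):
            p_fast = cache.sv_pvalue(j)
            p_ref = single_variant_score_test(null, panel.dosages[:, j])
            assert p_fast == pytest.approx(p_ref, rel=1e-10)

    def test_affine_covariate_recoding_invariance(self, rng):
        n = 500
        X = rng.standard_normal((n, 2))
        Y = rng.standard_normal(n) + X[:, 0]
        g = rng.binomial(2, 0.2, n).astype(float)
        p1 = single_variant_score_test(fit_null_model(Y, X), g)
        X2 = X * np.array([3.0, -0.5]) + np.array([10.0, -2.0])
        p2 = single_variant_score_test(fit_null_model(Y, X2), g)
        assert p1 == pytest.approx(p2, rel=1e-8)
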