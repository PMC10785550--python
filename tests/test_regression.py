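"""Per-gene regression: filters, design, fits, Wald tests, contrasts."""

import numpy as np
import pytest
from scipy import stats

from nichede.regression import (
    FitConfig,
    build_design,
    contrast_markers,
    fit_all_genes,
    fit_gene,
    select_testable,
    wald_one_sided,
)


class TestSelectTestable:
    def test_total_count_boundary_is_strict(self):
        counts = np.full((10, 1), 10)  # total exactly 100
        cells = np.ones((10, 1))
        niche = np.ones((10, 1))
        A = np.ones((1, 1))
        mask = select_testable(
            counts, cells, niche, A, min_total_count=100, min_pair_obs=5
        )
        assert not mask.any()
        mask = select_testable(
            counts, cells, niche, A, min_total_count=99, min_pair_obs=5
        )
        assert mask.all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        S, G, T = 40, 12, 3
        counts = rng.integers(0, 30, size=(S, G))
        cells = rng.uniform(0, 1, size=(S, T)) * (rng.random((S, T)) > 0.4)
        niche = rng.uniform(0, 1, size=(S, T)) * (rng.random((S, T)) > 0.3)
        A = rng.uniform(0, 5, size=(T, G))
        C, M, gamma = 150, 8, 60.0
        mask = select_testable(counts, cells, niche, A, C, M, gamma)
        cutoffs = [np.percentile(A[i], 100 - gamma) for i in range(T)]
        for g in range(G):
            for i in range(T):
                for n in range(T):
                    c1 = counts[:, g].sum() > C
                    c2 = np.sum((cells[:, i] > 0) & (niche[:, n] > 0)) > M
                    c3 = A[i, g] >= cutoffs[i]
                    assert mask[g, i, n] == (c1 and c2 and c3)


class TestBuildDesign:
    def test_elementwise_product_oracle(self):
        rng = np.random.default_rng(1)
        S, T = 20, 3
        p_gene = rng.uniform(0, 1, (S, T))
        niche = rng.normal(size=(S, T))
        pairs = [(0, 1), (2, 0), (1, 1)]
        X = build_design(p_gene, niche, pairs)
        for j, (i, n) in enumerate(pairs):
            np.testing.assert_allclose(X[:, j], p_gene[:, i] * niche[:, n])
        np.testing.assert_allclose(X[:, -1], 1.0)  # intercept

    def test_two_types_at_most_four_interaction_columns(self):
        pairs = [(i, n) for i in range(2) for n in range(2)]
        X = build_design(np.ones((5, 2)), np.ones((5, 2)), pairs)
        assert X.shape[1] == 4 + 1

    def test_single_cell_indicator_reduction(self):
        # with indicator p the columns reduce to N * I(label == i)
        labels = np.array([0, 1, 0])
        p_gene = np.eye(2)[labels]
        niche = np.arange(6, dtype=float).reshape(3, 2)
        X = build_design(p_gene, niche, [(0, 0), (1, 1)])
        np.testing.assert_allclose(X[:, 0], niche[:, 0] * (labels == 0))
        np.testing.assert_allclose(X[:, 1], niche[:, 1] * (labels == 1))


class TestFitGene:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(2)
        mu0 = rng.uniform(1, 10, size=200)
        y = rng.poisson(mu0 * 1.7)
        X = np.ones((200, 1))
        fit = fit_gene(y, X, np.log(mu0))
        assert fit.beta[0] == pytest.approx(np.log(y.sum() / mu0.sum()), abs=1e-8)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 300
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n), np.ones(n)])
        offset = rng.normal(1.0, 0.5, size=n)
        beta_true = np.array([0.3, -0.2, 0.5])
        y = rng.poisson(np.exp(offset + X @ beta_true))
        fit = fit_gene(y, X, offset)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)

    def test_null_estimates_unbiased(self):
        # simulated NB data with beta = 0: the mean estimate across genes
        # stays within 3 standard errors of zero
        rng = np.random.default_rng(4)
        n, n_genes = 400, 120
        x = rng.normal(size=n)
        X = np.column_stack([x, np.ones(n)])
        offset = np.log(rng.uniform(5, 20, size=n))
        betas, ses = [], []
        for _ in range(n_genes):
            mu = np.exp(offset)
            y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
            fit = fit_gene(y.astype(float), X, offset)
            betas.append(fit.beta[0])
            ses.append(fit.se[0])
        mean_beta = np.mean(betas)
        se_mean = np.std(betas) / np.sqrt(n_genes)
        assert abs(mean_beta) < 3 * se_mean + 1e-3

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        X = np.column_stack([x, np.ones(n)])
        offset = np.log(rng.uniform(5, 20, size=n))
        est = []
        for _ in range(40):
            mu = np.exp(offset + 0.5 * x)
            y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
            est.append(fit_gene(y.astype(float), X, offset).beta[0])
        assert 0.4 < np.mean(est) < 0.6

    def test_dispersion_estimate_near_truth(self):
        rng = np.random.default_rng(6)
        mu = np.full(3000, 10.0)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        fit = fit_gene(y.astype(float), np.ones((3000, 1)), np.log(mu))
        assert 0.7 < fit.dispersion < 1.4


class TestWald:
    def test_zero_beta_gives_half(self, small_null_results):
        st_ = small_null_results.stats[0]
        ft = small_null_results.fits[0]
        g, i, n = map(int, np.argwhere(ft.tested)[0])
        p_sum = st_.p_pos[g, i, n] + st_.p_neg[g, i, n]
        assert p_sum == pytest.approx(1.0, abs=1e-12)

    def test_normal_quantile(self):
        assert stats.norm.sf(1.6449) == pytest.approx(0.05, abs=1e-4)

    def test_tail_identity_on_fit(self, small_null_results):
        for st_, ft in zip(small_null_results.stats, small_null_results.fits):
            tested = ft.tested
            np.testing.assert_allclose(
                st_.p_pos[tested] + st_.p_neg[tested], 1.0, atol=1e-12
            )


class TestContrast:
    def _make_fit(self, beta, cov, pairs):
        from nichede.regression import NicheDEFit

        T = 2
        b = np.zeros((1, T, T))
        se = np.full((1, T, T), np.nan)
        tested = np.zeros((1, T, T), dtype=bool)
        for j, (i, n) in enumerate(pairs):
            b[0, i, n] = beta[j]
            se[0, i, n] = np.sqrt(cov[j, j])
            tested[0, i, n] = True
        return NicheDEFit(
            gene_names=["g"],
            type_names=["a", "b"],
            bandwidth=1.0,
            beta=b,
            se=se,
            tested=tested,
            loglik=np.zeros(1),
            dispersion=np.ones(1),
            converged=np.ones(1, bool),
            pair_index=[pairs],
            pair_cov=[cov],
        )

    def test_equal_betas_give_half(self):
        fit = self._make_fit([1.0, 1.0], np.diag([0.25, 0.25]), [(0, 0), (0, 1)])
        out = contrast_markers(fit, 0, 0, 0, 1)
        assert out["p_value"] == pytest.approx(0.5)
        assert out["statistic"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        fit = self._make_fit([1.0, 0.0], np.diag([0.25, 0.25]), [(0, 0), (0, 1)])
        out = contrast_markers(fit, 0, 0, 0, 1)
        assert out["statistic"] == pytest.approx(1.0 / np.sqrt(0.5), abs=1e-4)
        assert out["p_value"] == pytest.approx(0.0786, abs=2e-3)

    def test_matches_quadratic_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=(2, 2))
            cov = a @ a.T + 0.1 * np.eye(2)
            beta = rng.normal(size=2)
            fit = self._make_fit(beta, cov, [(0, 0), (0, 1)])
            out = contrast_markers(fit, 0, 0, 0, 1)
            c = np.array([1.0, -1.0])
            z = (c @ beta) / np.sqrt(c @ cov @ c)
            assert out["statistic"] == pytest.approx(z, rel=1e-10)

    def test_zero_variance_untestable(self):
        cov = np.ones((2, 2))  # perfectly correlated, equal variance
        fit = self._make_fit([1.0, 0.5], cov, [(0, 0), (0, 1)])
        out = contrast_markers(fit, 0, 0, 0, 1)
        assert not out["testable"]


class TestFitAllGenes:
    def test_untested_entries_fixed_at_zero(self, small_null_results):
        ft = small_null_results.fits[0]
        assert np.all(ft.beta[~ft.tested] == 0)
        assert np.all(np.isnan(ft.se[~ft.tested]))
        assert np.all(ft.se[ft.tested] > 0)

    def test_loglik_finite_for_converged_genes(self, small_null_results):
        ft = small_null_results.fits[0]
        assert np.all(np.isfinite(ft.loglik[ft.converged]))
        assert np.all(np.isfinite(ft.dispersion[ft.converged]))
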