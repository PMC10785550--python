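"""P-value combination and the hierarchical BH cascade."""

import numpy as np
import pytest
from scipy import stats

from nichede.multitest import (
    bh_reject,
    browns_combine,
    cauchy_combine,
    hierarchical_procedure,
    likelihood_weights,
)


class TestBrown:
    def test_single_p_returned_unchanged(self):
        assert browns_combine([0.123]) == pytest.approx(0.123)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            browns_combine([])

    def test_reduces_to_fisher_under_independence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.001, 0.999, size=4)
            fisher = stats.chi2.sf(-2 * np.sum(np.log(p)), 8)
            assert browns_combine(p, np.eye(4)) == pytest.approx(fisher, abs=1e-10)

    def test_equicorrelated_matches_monte_carlo(self):
        # 200k draws of 5 equicorrelated (rho = 0.5) one-sided normal
        # p-values give the empirical null of the combined p
        rho, k, n_mc = 0.5, 5, 200_000
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(n_mc)
        z = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
            (n_mc, k)
        )
        x_mc = -2 * np.log(stats.norm.sf(z)).sum(axis=1)
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        for target in (0.01, 0.05, 0.2):
            # threshold x with combined p == target under the approximation
            lo, hi = 1.0, 200.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                p_mid = browns_combine(
                    np.exp(-np.full(k, mid) / (2 * k)), corr
                )  # p-vector with sum -2 log p == mid
                lo, hi = (mid, hi) if p_mid > target else (lo, mid)
            thresh = 0.5 * (lo + hi)
            emp = np.mean(x_mc > thresh)
            mc_se = np.sqrt(target * (1 - target) / n_mc)
            assert abs(emp - target) < 2 * mc_se + 0.004

    def test_monotone_in_evidence(self):
        corr = np.full((3, 3), 0.3)
        np.fill_diagonal(corr, 1.0)
        strong = browns_combine([0.001, 0.01, 0.02], corr)
        weak = browns_combine([0.2, 0.4, 0.6], corr)
        assert strong < weak


class TestCauchy:
    def test_identical_pvalues_inverted_exactly(self):
        for p in (0.01, 0.3, 0.5, 0.9):
            assert cauchy_combine([p, p, p]) == pytest.approx(p, abs=1e-12)

    def test_half_stays_half(self):
        assert cauchy_combine([0.5, 0.5], [0.9, 0.1]) == pytest.approx(0.5, abs=1e-12)

    def test_uniform_null_stays_uniform(self):
        rng = np.random.default_rng(2)
        combined = [
            cauchy_combine(rng.uniform(size=3), rng.dirichlet(np.ones(3)))
            for _ in range(5000)
        ]
        ks = stats.kstest(combined, "uniform")
        assert ks.pvalue > 0.01

    def test_dominated_by_smallest_p(self):
        assert cauchy_combine([1e-10, 0.5], [0.5, 0.5]) < 1e-8


class TestLikelihoodWeights:
    def test_equal_logliks_give_uniform(self):
        np.testing.assert_allclose(likelihood_weights([-50.0, -50.0, -50.0]), 1 / 3)

    def test_single_bandwidth_gets_weight_one(self):
        np.testing.assert_allclose(likelihood_weights([-123.0]), [1.0])

    def test_literal_ratio_for_same_sign_logliks(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            ll = rng.normal(-1000, 30, size=3)
            w = likelihood_weights(ll)
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)
            np.testing.assert_allclose(w, ll / ll.sum())
            # similar-magnitude log-likelihoods give near-uniform weights,
            # which keeps the Cauchy combination calibrated under the null
            assert np.all(np.abs(w - 1 / 3) < 0.05)

    def test_mixed_signs_fall_back_to_uniform(self):
        np.testing.assert_allclose(likelihood_weights([-5.0, 5.0]), 0.5)


class TestBH:
    def test_all_small_rejected(self):
        assert len(bh_reject(np.full(10, 0.01), 0.05)) == 10

    def test_hand_executed_step_up(self):
        rejected = bh_reject(np.array([0.01, 0.04, 0.2]), 0.05)
        assert list(rejected) == [0]

    def test_empty_input(self):
        assert len(bh_reject(np.array([]), 0.05)) == 0

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 30))
            alpha = rng.uniform(0.01, 0.2)
            got = set(bh_reject(p, alpha))
            order = np.argsort(p)
            m = len(p)
            k_max = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * alpha / m:
                    k_max = rank
            expected = set(order[:k_max].tolist())
            assert got == expected


class TestHierarchy:
    def test_no_gene_rejection_gates_everything(self, small_null_results):
        disc, _ = small_null_results.hierarchy(1e-12)
        assert disc.genes == set()
        assert disc.pairs == set()
        assert disc.triples == set()

    def test_fdr_bound_formula(self):
        # alpha (D + F) / (D + 1) with D=9, F=10 gives 0.095
        assert 0.05 * (9 + 10) / (9 + 1) == pytest.approx(0.095)

    def test_structural_hierarchy_invariant(self, small_null_results):
        disc, _ = small_null_results.hierarchy(0.3)
        for g, i, n, _s in disc.triples:
            assert (g, i) in disc.pairs
        for g, i in disc.pairs:
            assert g in disc.genes

    def test_monotone_in_alpha(self, small_null_results):
        d1, _ = small_null_results.hierarchy(0.05)
        d2, _ = small_null_results.hierarchy(0.2)
        assert d1.genes <= d2.genes
        assert d1.pairs <= d2.pairs
        assert d1.triples_unsigned() <= d2.triples_unsigned()

    def test_reported_bound_consistent(self, small_null_results):
        disc, _ = small_null_results.hierarchy(0.05)
        assert disc.fdr_bound >= 0.05 or disc.n_families == 0

    def test_pooled_equals_per_bandwidth_when_identical(self, small_null_results):
        # a gene fitted at one bandwidth only gets that bandwidth's p back
        _, hier = small_null_results.hierarchy(0.05)
        K = len(hier.bandwidths)
        for g in range(len(hier.gene_names)):
            per = hier.per_bandwidth_gene["pos"][:, g]
            if np.isfinite(per).sum() == 1 and np.isfinite(hier.weights[g]).sum() == 1:
                (k,) = np.nonzero(np.isfinite(per))[0]
                assert hier.pooled_gene["pos"][g] == pytest.approx(per[k], abs=1e-9)
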