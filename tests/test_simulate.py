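"""Synthetic data generation and benchmark primitives."""

import numpy as np
import pytest

from nichede.multitest import DiscoverySet
from nichede.simulate import (
    SimConfig,
    aggregate_pseudospots,
    apply_bleeding,
    apply_spikein,
    bootstrap_dataset,
    generate_fixture,
    score_recovery,
    simulate_null_counts,
)


class TestGenerateFixture:
    def test_same_seed_identical_output(self):
        a = generate_fixture(SimConfig(n_obs=100, n_genes=40, seed=5))
        b = generate_fixture(SimConfig(n_obs=100, n_genes=40, seed=5))
        np.testing.assert_array_equal(
            a.reference.mean_expression, b.reference.mean_expression
        )
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.cell_counts, b.cell_counts)

    def test_markers_enriched_in_home_type(self):
        fx = generate_fixture(SimConfig(n_obs=50, n_genes=200, n_types=4, seed=6))
        A = fx.reference.mean_expression
        for t, tname in enumerate(fx.type_names):
            for g in fx.marker_genes[tname]:
                others = np.delete(A[:, g], t)
                assert A[t, g] >= 5.0 * others.max()

    def test_composition_rows_sum_to_one(self):
        fx = generate_fixture(SimConfig(n_obs=80, n_genes=30, seed=7))
        np.testing.assert_allclose(fx.composition.proportions.sum(axis=1), 1.0)

    def test_single_cell_mode_gives_indicators(self):
        fx = generate_fixture(
            SimConfig(n_obs=60, n_genes=30, seed=8, resolution="single_cell")
        )
        assert fx.composition.mode == "labels"
        assert set(np.unique(fx.cell_counts)) <= {0.0, 1.0}


class TestNullCounts:
    def test_zero_mean_gives_zero_count(self):
        mu = np.array([[0.0, 5.0]])
        counts = simulate_null_counts(mu, 1.0, np.random.default_rng(0))
        assert counts[0, 0] == 0

    def test_moments_match_nb(self):
        # size 1, mu 10: mean 10, variance mu + mu^2 = 110
        rng = np.random.default_rng(1)
        draws = simulate_null_counts(np.full((50_000, 1), 10.0), 1.0, rng)[:, 0]
        se_mean = np.sqrt(110 / 50_000)
        assert abs(draws.mean() - 10) < 3 * se_mean
        # variance of the sample variance for NB is dominated by kurtosis;
        # a generous 10% band is still far tighter than any failure mode
        assert abs(draws.var() - 110) / 110 < 0.1


class TestSpikein:
    def test_zero_beta_is_identity(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(1, 5, (10, 6))
        p = rng.uniform(0, 1, (10, 3, 6))
        niche = rng.normal(size=(10, 3))
        out = apply_spikein(mu, p, niche, (0, 1), np.arange(3), 0.0)
        np.testing.assert_array_equal(out, mu)

    def test_matches_exponential_oracle(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(1, 5, (8, 5))
        p = rng.uniform(0, 1, (8, 2, 5))
        niche = rng.normal(size=(8, 2))
        genes = np.array([1, 3])
        beta = 0.7
        out = apply_spikein(mu, p, niche, (1, 0), genes, beta)
        for s in range(8):
            for g in range(5):
                factor = np.exp(p[s, 1, g] * beta * niche[s, 0]) if g in genes else 1.0
                assert out[s, g] == pytest.approx(mu[s, g] * factor, rel=1e-12)


class TestBleeding:
    def test_zero_alpha_identity(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(1, 5, (12, 4))
        coords = rng.uniform(0, 5, (12, 2))
        np.testing.assert_array_equal(apply_bleeding(mu, 0.0, 1.0, coords), mu)

    def test_mass_conserved_per_gene(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(1, 5, (30, 6))
        coords = rng.uniform(0, 5, (30, 2))
        out = apply_bleeding(mu, 0.25, 0.8, coords)
        np.testing.assert_allclose(out.sum(axis=0), mu.sum(axis=0), rtol=1e-8)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            apply_bleeding(np.ones((2, 2)), 0.25, 0.0, np.zeros((2, 2)))

    def test_per_gene_alpha(self):
        rng = np.random.default_rng(6)
        mu = rng.uniform(1, 5, (10, 2))
        coords = rng.uniform(0, 3, (10, 2))
        alpha = np.array([0.0, 0.5])
        out = apply_bleeding(mu, alpha, 1.0, coords)
        np.testing.assert_array_equal(out[:, 0], mu[:, 0])
        assert not np.allclose(out[:, 1], mu[:, 1])


class TestBootstrap:
    def test_identity_indices_preserve_means(self):
        rng = np.random.default_rng(7)
        mu = rng.uniform(1, 5, (20, 3))
        niche = rng.normal(size=(20, 2))
        nb, counts, idx = bootstrap_dataset(
            niche, mu, 20, rng, indices=np.arange(20)
        )
        np.testing.assert_array_equal(nb, niche)
        assert counts.shape == (20, 3)

    def test_output_row_count(self):
        rng = np.random.default_rng(8)
        nb, counts, idx = bootstrap_dataset(
            np.zeros((10, 2)), np.ones((10, 3)), 57, rng
        )
        assert counts.shape[0] == 57 and nb.shape[0] == 57 and idx.shape[0] == 57

    def test_resample_frequencies_near_uniform(self):
        rng = np.random.default_rng(9)
        _, _, idx = bootstrap_dataset(np.zeros((50, 1)), np.ones((50, 1)), 50_000, rng)
        freq = np.bincount(idx, minlength=50) / 50_000
        # multinomial expectation 1/50 with se ~ sqrt(p(1-p)/n)
        assert np.all(np.abs(freq - 0.02) < 5 * np.sqrt(0.02 * 0.98 / 50_000))


class TestPseudospots:
    def test_tiny_side_is_identity(self):
        rng = np.random.default_rng(10)
        coords = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        counts = rng.integers(0, 5, (3, 4))
        cells = rng.uniform(0, 2, (3, 2))
        c2, counts2, cells2, size = aggregate_pseudospots(coords, counts, cells, 0.5)
        assert size == 1.0
        assert counts2.sum() == counts.sum()
        np.testing.assert_array_equal(np.sort(counts2.sum(axis=1)), np.sort(counts.sum(axis=1)))

    def test_counts_conserved_exactly(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 10, (40, 2))
        counts = rng.integers(0, 8, (40, 5))
        cells = rng.uniform(0, 2, (40, 3))
        _, counts2, cells2, _ = aggregate_pseudospots(coords, counts, cells, 2.5)
        np.testing.assert_array_equal(counts2.sum(axis=0), counts.sum(axis=0))
        np.testing.assert_allclose(cells2.sum(axis=0), cells.sum(axis=0))

    def test_spot_size_counting_oracle(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 6, (30, 2))
        side = 2.0
        _, _, _, size = aggregate_pseudospots(
            coords, np.ones((30, 1), dtype=int), np.ones((30, 1)), side
        )
        origin = coords.min(axis=0)
        squares = {tuple(np.floor((c - origin) / side).astype(int)) for c in coords}
        assert size == pytest.approx(30 / len(squares))


class TestScoreRecovery:
    def test_perfect_recovery(self):
        gold = DiscoverySet(alpha=0.05, genes={1, 2}, pairs={(1, 0)}, triples={(1, 0, 1, 1)})
        out = score_recovery(gold, gold, {0, 1, 2, 3}, {(1, 0), (2, 2)}, {(1, 0, 1), (3, 0, 0)})
        for level in ("gene", "cell_type", "interaction"):
            assert out[level].sensitivity == 1.0
            assert out[level].specificity == 1.0

    def test_disjoint_gives_zero_sensitivity(self):
        gold = DiscoverySet(alpha=0.05, genes={1})
        test = DiscoverySet(alpha=0.05, genes={2})
        out = score_recovery(gold, test, {1, 2, 3}, set(), set())
        assert out["gene"].sensitivity == 0.0

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(13)
        universe = set(range(30))
        gold_g = set(rng.choice(30, 8, replace=False).tolist())
        test_g = set(rng.choice(30, 10, replace=False).tolist())
        gold = DiscoverySet(alpha=0.05, genes=gold_g)
        test = DiscoverySet(alpha=0.05, genes=test_g)
        out = score_recovery(gold, test, universe, set(), set())
        assert out["gene"].sensitivity == len(gold_g & test_g) / len(gold_g)
        comp = universe - gold_g
        assert out["gene"].specificity == len(comp - test_g) / len(comp)
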