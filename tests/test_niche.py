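"""Effective-niche geometry: kernel, smoothing, standardization, harmonize."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichede.niche import (
    compute_effective_niche,
    default_bandwidths,
    gaussian_kernel,
    harmonize_samples,
    harmonize_scale_factor,
    standardize_niche,
)


class TestGaussianKernel:
    def test_closed_form_at_zero(self):
        assert gaussian_kernel(0.0, 1.0) == pytest.approx(0.3989423, abs=1e-7)
        assert gaussian_kernel(0.0, 2.0) == pytest.approx(0.1994711, abs=1e-7)

    @given(
        st.floats(0, 50),
        st.floats(0, 50),
        st.floats(0.1, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_distance(self, d1, d2, sigma):
        lo, hi = sorted((d1, d2))
        if hi - lo < 1e-3:  # below float resolution of exp(-z^2/2)
            return
        if gaussian_kernel(lo, sigma) == 0.0:  # both underflow far in the tail
            return
        assert gaussian_kernel(lo, sigma) > gaussian_kernel(hi, sigma)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_bandwidth_rejected(self, bad):
        with pytest.raises(ValueError):
            gaussian_kernel(1.0, bad)


class TestEffectiveNiche:
    def test_two_cells_two_term_sum(self):
        coords = np.array([[0.0, 0.0], [3.0, 0.0]])
        counts = np.array([[1.0, 0.0], [0.0, 1.0]])  # types A, B
        niche = compute_effective_niche(coords, counts, sigma=2.0)
        expected = [gaussian_kernel(0.0, 2.0), gaussian_kernel(3.0, 2.0)]
        np.testing.assert_allclose(niche.matrix[0], expected, rtol=1e-12)

    def test_isolated_cell_self_only(self):
        coords = np.array([[0.0, 0.0], [1e6, 1e6]])
        counts = np.array([[1.0, 0.0], [0.0, 1.0]])
        niche = compute_effective_niche(coords, counts, sigma=1.0)
        assert niche.matrix[0, 0] == pytest.approx(gaussian_kernel(0.0, 1.0))
        assert niche.matrix[0, 1] == 0.0  # kernel underflows at 1e6 sigmas

    def test_exclude_self_drops_diagonal_term(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        counts = np.array([[1.0, 0.0], [0.0, 1.0]])
        niche = compute_effective_niche(coords, counts, 1.0, include_self=False)
        assert niche.matrix[0, 0] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        S, T = 50, 3
        coords = rng.uniform(0, 10, size=(S, 2))
        counts = rng.uniform(0, 4, size=(S, T))
        sigma = 1.7
        niche = compute_effective_niche(coords, counts, sigma)
        oracle = np.zeros((S, T))
        for s in range(S):
            for sp in range(S):
                d = np.hypot(*(coords[s] - coords[sp]))
                for t in range(T):
                    oracle[s, t] += gaussian_kernel(d, sigma) * counts[sp, t]
        np.testing.assert_allclose(niche.matrix, oracle, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 5, size=(30, 2))
        counts = rng.uniform(0, 2, size=(30, 2))
        perm = rng.permutation(30)
        base = compute_effective_niche(coords, counts, 1.0).matrix
        permuted = compute_effective_niche(coords[perm], counts[perm], 1.0).matrix
        np.testing.assert_allclose(permuted, base[perm], rtol=1e-12)

    def test_coordinate_and_bandwidth_scaling(self):
        # doubling all coordinates and sigma halves the kernel prefactor,
        # so the niche matrix scales by exactly 1/2
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 5, size=(20, 2))
        counts = rng.uniform(0, 2, size=(20, 2))
        base = compute_effective_niche(coords, counts, 1.3).matrix
        scaled = compute_effective_niche(2 * coords, counts, 2.6).matrix
        np.testing.assert_allclose(scaled, base / 2.0, rtol=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_effective_niche(np.zeros((0, 2)), np.zeros((0, 2)), 1.0)


class TestStandardize:
    def test_columns_centered_and_scaled(self):
        rng = np.random.default_rng(14)
        niche = compute_effective_niche(
            rng.uniform(0, 5, (40, 2)), rng.uniform(0, 3, (40, 3)), 1.0
        )
        std = standardize_niche(niche)
        assert np.all(np.abs(std.matrix.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(std.matrix.std(axis=0) - 1) < 1e-10)
        assert std.standardized

    def test_constant_column_excluded(self):
        niche = compute_effective_niche(
            np.array([[0.0, 0], [1, 0]]), np.array([[1.0, 0], [1.0, 0]]), 1e6
        )
        # with a huge bandwidth both rows see the same composition
        std = standardize_niche(niche)
        assert 0 in std.excluded_types or 1 in std.excluded_types
        for j in std.excluded_types:
            assert np.all(std.matrix[:, j] == 0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(15)
        niche = compute_effective_niche(
            rng.uniform(0, 5, (30, 2)), rng.uniform(0, 3, (30, 2)), 1.0
        )
        once = standardize_niche(niche)
        twice = standardize_niche(once)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-12)


class TestHarmonize:
    @pytest.mark.parametrize(
        "r,q,nr,nq,expected",
        [(1.0, 1.0, 5.0, 5.0, 1.0), (1.0, 1.0, 10.0, 5.0, 2.0), (1.0, 2.0, 5.0, 5.0, 4.0)],
    )
    def test_scale_factor_arithmetic(self, r, q, nr, nq, expected):
        assert harmonize_scale_factor(r, q, nr, nq) == pytest.approx(expected)

    def test_stacks_with_batch_labels_and_scaling(self):
        rng = np.random.default_rng(16)
        n1 = compute_effective_niche(rng.uniform(0, 5, (10, 2)), rng.uniform(0, 2, (10, 2)), 1.0)
        n2 = compute_effective_niche(rng.uniform(0, 5, (8, 2)), rng.uniform(0, 2, (8, 2)), 1.0)
        pooled, labels = harmonize_samples(
            [n1, n2],
            ["ref", "qry"],
            "ref",
            spot_radii={"ref": 1.0, "qry": 1.0},
            mean_cells={"ref": 4.0, "qry": 2.0},
        )
        assert pooled.matrix.shape == (18, 2)
        assert list(labels[:10]) == ["ref"] * 10
        np.testing.assert_allclose(pooled.matrix[10:], n2.matrix * 2.0)

    def test_missing_radius_rejected(self):
        n1 = compute_effective_niche(np.zeros((2, 2)), np.ones((2, 1)), 1.0)
        with pytest.raises(ValueError, match="missing radius"):
            harmonize_samples(
                [n1, n1], ["a", "b"], "a", spot_radii={"a": 1.0}, mean_cells={"a": 1.0}
            )


def test_default_bandwidths_are_distance_percentiles():
    rng = np.random.default_rng(17)
    coords = rng.uniform(0, 100, size=(60, 2))
    bws = default_bandwidths(coords)
    from scipy.spatial.distance import pdist

    expected = np.percentile(pdist(coords), [1, 5, 10])
    np.testing.assert_allclose(bws, expected, rtol=1e-12)
    assert bws == sorted(bws)
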