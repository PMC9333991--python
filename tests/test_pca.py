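import warnings

import numpy as np
import pytest

from mesomap.atlas import make_atlas
from mesomap.pca import (derive_rois, permutation_eigen_test,
                         recovery_difference, recovery_matrix, spatial_pca,
                         _double_center)
from mesomap.rsfc import CorrMatrix


def sym_matrix(z):
    z = np.asarray(z, float)
    return CorrMatrix(z=z, index=tuple(range(z.shape[0])), kind="roi")


def centered_basis(n, k, seed=0):
    """k orthonormal vectors orthogonal to the ones vector."""
    rng = np.random.default_rng(seed)
    a = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
    q, _ = np.linalg.qr(a)
    return q[:, 1:k + 1]


class TestSpatialPCA:
    def test_rank_one_matrix_recovers_direction(self):
        v = centered_basis(12, 1)[:, 0]
        res = spatial_pca(sym_matrix(np.outer(v, v)))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        cosine = abs(res.components[:, 0] @ v)
        assert cosine == pytest.approx(1.0, abs=1e-9)

    def test_zero_matrix_all_zero_eigenvalues(self):
        res = spatial_pca(sym_matrix(np.zeros((6, 6))))
        assert np.allclose(res.eigenvalues, 0.0)

    def test_planted_rank_two_ratio(self):
        q = centered_basis(20, 2)
        m = 52 * np.outer(q[:, 0], q[:, 0]) + 18 * np.outer(q[:, 1], q[:, 1])
        res = spatial_pca(sym_matrix(m))
        assert res.variance_explained[0] == pytest.approx(52 / 70, abs=1e-6)
        assert res.variance_explained[1] == pytest.approx(18 / 70, abs=1e-6)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((15, 15))
        z = (z + z.T) / 2
        res = spatial_pca(sym_matrix(z))
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(_double_center(z)), abs=1e-9)

    def test_components_orthogonal_and_descending(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((10, 10))
        z = (z + z.T) / 2
        res = spatial_pca(sym_matrix(z))
        gram = res.components.T @ res.components
        assert np.allclose(gram, np.eye(10), atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_asymmetric_input_rejected(self):
        z = np.arange(9, dtype=float).reshape(3, 3)
        with pytest.raises(ValueError):
            spatial_pca(CorrMatrix(z=z, index=(0, 1, 2), kind="roi"))


class TestPermutationTest:
    @staticmethod
    def draw_mice(rng, n_mice, n_units, shift=0.0):
        mats = []
        block = np.zeros((n_units, n_units))
        block[:4, :4] = 1.0
        np.fill_diagonal(block, 0.0)
        for i in range(n_mice):
            w = rng.standard_normal((n_units, n_units))
            m = 0.2 * (w + w.T) / np.sqrt(2)
            mats.append(m + shift * block)
        return mats

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        mats = self.draw_mice(rng, 8, 10)
        labels = np.arange(8) < 4
        r1 = permutation_eigen_test(mats, labels, n=50, seed=5)
        r2 = permutation_eigen_test(mats, labels, n=50, seed=5)
        assert np.array_equal(r1.null_eigenvalues, r2.null_eigenvalues)
        assert np.array_equal(r1.significant, r2.significant)

    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(1)
        n_units = 12
        mats = (self.draw_mice(rng, 6, n_units, shift=1.0)
                + self.draw_mice(rng, 6, n_units, shift=0.0))
        labels = np.arange(12) < 6
        res = permutation_eigen_test(mats, labels, n=500, seed=2)
        assert res.significant[0]

    def test_type_one_rate_under_null(self):
        """Exchangeable groups: the 90th-percentile criterion fires ~10%."""
        from mesomap.experiments import permutation_calibration
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_calibration(0, n_runs=100, n_iterations=100)
        assert res["rate"] == pytest.approx(0.10, abs=0.09)

    def test_too_few_mice_rejected(self):
        rng = np.random.default_rng(0)
        mats = self.draw_mice(rng, 4, 6)
        with pytest.raises(ValueError):
            permutation_eigen_test(mats, np.array([1, 1, 0, 0], bool), n=10)


class TestDeriveRois:
    @staticmethod
    def blob_map(atlas, centers, sign=1.0, sigma=2.5):
        rows = np.arange(atlas.height)[:, None]
        cols = np.arange(atlas.width)[None, :]
        m = np.zeros(atlas.shape)
        for (r, c) in centers:
            m += sign * np.exp(-((rows - r) ** 2 + (cols - c) ** 2)
                               / (2 * sigma ** 2))
        return m

    def test_symmetric_blob_pair_yields_one_roi_per_hemisphere(self):
        atlas = make_atlas(64, 64)
        m = self.blob_map(atlas, [(30, 20), (30, 43)])
        rs = derive_rois(m, atlas)
        assert rs.per_hemisphere == {"left": 1, "right": 1}

    def test_uniform_map_single_component_per_hemisphere(self):
        atlas = make_atlas(64, 64)
        m = np.where(atlas.brain_mask, 1.0, 0.0)
        rs = derive_rois(m, atlas, smooth_sigma=0.0, threshold_frac=0.0)
        assert rs.per_hemisphere["left"] == 1
        assert rs.per_hemisphere["right"] == 1

    def test_seven_planted_blob_pairs_recovered(self):
        atlas = make_atlas(128, 128)
        rows = [15, 30, 45, 60, 75, 90, 105]
        centers = [(r, 40) for r in rows]
        m = self.blob_map(atlas, centers, sigma=3.0)
        rs = derive_rois(m, atlas, smooth_sigma=1.0, threshold_frac=0.5)
        assert rs.per_hemisphere == {"left": 7, "right": 7}

    def test_mirror_invariance(self):
        atlas = make_atlas(64, 64)
        m = self.blob_map(atlas, [(25, 18)]) - self.blob_map(atlas, [(45, 40)])
        r1 = derive_rois(m, atlas)
        r2 = derive_rois(m[:, ::-1], atlas)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_empty_threshold_warns(self):
        atlas = make_atlas(64, 64)
        with pytest.warns(UserWarning, match="empty"):
            rs = derive_rois(np.zeros(atlas.shape), atlas)
        assert len(rs) == 0


class TestRecovery:
    def rand_mats(self, rng, n_mice, n=5, scale=0.3):
        out = []
        for _ in range(n_mice):
            w = rng.standard_normal((n, n)) * scale
            m = (w + w.T) / 2
            np.fill_diagonal(m, 0.0)
            out.append(m)
        return out

    def test_no_change_gives_zero_matrix(self):
        rng = np.random.default_rng(0)
        mats = self.rand_mats(rng, 4)
        rec = recovery_matrix(mats, [m.copy() for m in mats])
        assert np.allclose(rec.values, 0.0)

    def test_planted_edge_change_recovered(self):
        rng = np.random.default_rng(1)
        week1 = self.rand_mats(rng, 6, scale=0.05)
        week4 = []
        for m in week1:
            m4 = m.copy()
            m4[0, 1] = m4[1, 0] = abs(m[0, 1]) + 0.3  # |z| increase of ~0.3
            week4.append(m4)
        rec = recovery_matrix(week4, week1)
        assert rec.values[0, 1] == pytest.approx(0.3, abs=0.05)

    def test_antisymmetric_under_week_swap(self):
        rng = np.random.default_rng(2)
        w1 = self.rand_mats(rng, 4)
        w4 = self.rand_mats(rng, 4)
        fwd = recovery_matrix(w4, w1).values
        rev = recovery_matrix(w1, w4).values
        assert np.allclose(fwd, -rev)

    def test_difference_identical_groups_no_edges(self):
        rng = np.random.default_rng(3)
        w1 = self.rand_mats(rng, 5)
        w4 = self.rand_mats(rng, 5)
        diff, edges = recovery_difference(w4, w1, [m.copy() for m in w4],
                                          [m.copy() for m in w1])
        assert np.allclose(diff, 0.0)
        assert edges == []

    def test_planted_suppressed_edge_emitted(self):
        rng = np.random.default_rng(4)
        a1 = self.rand_mats(rng, 6, scale=0.02)
        b1 = self.rand_mats(rng, 6, scale=0.02)
        a4 = [m.copy() for m in a1]
        b4 = []
        for m in b1:
            m4 = m.copy()
            m4[0, 1] = m4[1, 0] = abs(m[0, 1]) + 0.5
            b4.append(m4)
        diff, edges = recovery_difference(a4, a1, b4, b1)
        assert len(edges) == 1
        edge = edges[0]
        assert edge["sign"] == -1
        assert edge["delta_z"] == pytest.approx(diff[0, 1])
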