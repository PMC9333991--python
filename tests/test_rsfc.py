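import numpy as np
import pytest

from mesomap.rsfc import (CorrMatrix, SeedROI, corr_matrix,
                          difference_matrix, fisher_z, node_degree,
                          roi_timecourse, seed_map)

from conftest import movie_from_hbt


def roi_at(shape, *pixels):
    m = np.zeros(shape, bool)
    for r, c in pixels:
        m[r, c] = True
    return SeedROI(name="roi", pixels=m)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, size=20)
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_value_at_0p4(self):
        # 0.5 ln(1.4/0.6)
        assert fisher_z(0.4) == pytest.approx(0.42364893, abs=1e-6)

    def test_clips_perfect_correlation(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestRoiTimecourse:
    def test_single_pixel_roi_returns_trace(self, rng):
        hbt = rng.normal(size=(30, 4, 4))
        m = movie_from_hbt(hbt)
        tc = roi_timecourse(m, roi_at((4, 4), (2, 3)))
        assert np.array_equal(tc, hbt[:, 2, 3])

    def test_opposite_traces_cancel(self):
        hbt = np.zeros((20, 2, 2))
        x = np.sin(np.arange(20))
        hbt[:, 0, 0] = x
        hbt[:, 0, 1] = -x
        tc = roi_timecourse(movie_from_hbt(hbt), roi_at((2, 2), (0, 0), (0, 1)))
        assert np.allclose(tc, 0.0)

    def test_matches_explicit_loop_mean(self, rng):
        hbt = rng.normal(size=(15, 5, 5))
        pix = [(0, 1), (2, 2), (4, 3)]
        tc = roi_timecourse(movie_from_hbt(hbt), roi_at((5, 5), *pix))
        expected = np.mean([hbt[:, r, c] for r, c in pix], axis=0)
        assert np.allclose(tc, expected)

    def test_empty_intersection_rejected(self, rng):
        hbt = rng.normal(size=(10, 3, 3))
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        m = movie_from_hbt(hbt, mask=mask)
        with pytest.raises(ValueError):
            roi_timecourse(m, roi_at((3, 3), (2, 2)))


class TestSeedMap:
    def test_seed_with_itself_is_clipped_max(self, rng):
        hbt = rng.normal(size=(50, 3, 3))
        with pytest.warns(UserWarning):
            z = seed_map(movie_from_hbt(hbt), roi_at((3, 3), (1, 1)))
        assert z[1, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_noise_stays_near_zero(self, rng):
        hbt = rng.normal(size=(300, 4, 4))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = seed_map(movie_from_hbt(hbt), roi_at((4, 4), (0, 0)))
        others = np.delete(z.ravel(), 0)
        assert np.abs(others).max() < 0.35  # ~6 SE at n=300

    def test_planted_partner_correlation_recovered(self, rng):
        n = 300
        base = rng.normal(size=n)
        partner = 0.7 * base + np.sqrt(1 - 0.49) * rng.normal(size=n)
        hbt = rng.normal(size=(n, 3, 3))
        hbt[:, 0, 0] = base
        hbt[:, 2, 2] = partner
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = seed_map(movie_from_hbt(hbt), roi_at((3, 3), (0, 0)))
        assert z[2, 2] == pytest.approx(np.arctanh(0.7), abs=2 / np.sqrt(n - 3))


class TestCorrMatrix:
    def test_matches_nested_loop_oracle(self, rng):
        hbt = rng.normal(size=(40, 1, 5))
        m = movie_from_hbt(hbt)
        rois = [roi_at((1, 5), (0, i)) for i in range(5)]
        cm = corr_matrix(m, rois=rois)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert cm.z[i, j] == 0.0
                else:
                    r = np.corrcoef(hbt[:, 0, i], hbt[:, 0, j])[0, 1]
                    assert cm.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_independent_noise_mean_offdiag_near_zero(self, rng):
        hbt = rng.normal(size=(500, 6, 6))
        cm = corr_matrix(movie_from_hbt(hbt), spatial_downsample=1)
        assert abs(cm.offdiag().mean()) < 0.02

    def test_invariant_to_affine_rescaling(self, rng):
        hbt = rng.normal(size=(60, 1, 4))
        m1 = movie_from_hbt(hbt)
        hbt2 = hbt.copy()
        hbt2[:, 0, 2] = 5.0 * hbt2[:, 0, 2] - 3.0
        m2 = movie_from_hbt(hbt2)
        rois = [roi_at((1, 4), (0, i)) for i in range(4)]
        assert np.allclose(corr_matrix(m1, rois=rois).z,
                           corr_matrix(m2, rois=rois).z, atol=1e-10)

    def test_zero_variance_unit_flagged(self, rng):
        hbt = rng.normal(size=(30, 1, 3))
        hbt[:, 0, 1] = 2.0
        rois = [roi_at((1, 3), (0, i)) for i in range(3)]
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = corr_matrix(movie_from_hbt(hbt), rois=rois)
        assert cm.bad_units[1]
        assert np.isnan(cm.z[1, 0])


class TestNodeDegree:
    def test_fully_connected_four_units(self):
        z = np.full((4, 4), 1.0)
        cm = CorrMatrix(z=z, index=tuple(range(4)), kind="roi")
        nd = node_degree(cm, thr_z=0.4)
        assert np.all(nd.degree == 3)

    def test_all_subthreshold_gives_zero(self, rng):
        z = rng.uniform(-0.3, 0.39, size=(6, 6))
        z = (z + z.T) / 2
        cm = CorrMatrix(z=z, index=tuple(range(6)), kind="roi")
        assert np.all(node_degree(cm, 0.4).degree == 0)

    def test_matches_brute_force_count(self, rng):
        z = rng.uniform(-1, 1, size=(20, 20))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        cm = CorrMatrix(z=z, index=tuple(range(20)), kind="roi")
        nd = node_degree(cm, 0.4)
        for i in range(20):
            brute = sum(1 for j in range(20) if j != i and z[i, j] >= 0.4)
            assert nd.degree[i] == brute

    def test_monotone_in_threshold(self, rng):
        z = rng.uniform(-1, 1, size=(15, 15))
        z = (z + z.T) / 2
        cm = CorrMatrix(z=z, index=tuple(range(15)), kind="roi")
        degrees = [node_degree(cm, thr).degree.sum()
                   for thr in (0.2, 0.4, 0.6, 0.8)]
        assert degrees == sorted(degrees, reverse=True)

    def test_planted_hub_has_highest_degree(self, rng):
        """A node correlated >=0.5 with many others out-degrees the rest."""
        n, t = 12, 400
        hub = rng.normal(size=t)
        traces = np.empty((t, n))
        traces[:, 0] = hub
        for j in range(1, 8):
            traces[:, j] = 0.7 * hub + np.sqrt(1 - 0.49) * rng.normal(size=t)
        for j in range(8, n):
            traces[:, j] = rng.normal(size=t)
        hbt = traces[:, None, :]
        rois = [roi_at((1, n), (0, j)) for j in range(n)]
        cm = corr_matrix(movie_from_hbt(hbt), rois=rois)
        nd = node_degree(cm, 0.4)
        assert nd.degree[0] > np.median(nd.degree[8:])


class TestDifferenceMatrix:
    def make(self, z):
        return CorrMatrix(z=np.asarray(z, float), index=(0, 1), kind="roi")

    def test_equal_groups_give_zero(self):
        a = self.make([[0, 0.5], [0.5, 0]])
        assert np.allclose(difference_matrix([a, a], [a, a]).z, 0.0)

    def test_zero_reference_returns_mean(self):
        a = self.make([[0, 0.6], [0.6, 0]])
        b = self.make([[0, 0.2], [0.2, 0]])
        zero = self.make([[0, 0.0], [0.0, 0]])
        d = difference_matrix([a, b], [zero, zero])
        assert d.z[0, 1] == pytest.approx(0.4)

    def test_antisymmetric_under_group_swap(self):
        a = self.make([[0, 0.6], [0.6, 0]])
        b = self.make([[0, 0.1], [0.1, 0]])
        ab = difference_matrix([a], [b]).z
        ba = difference_matrix([b], [a]).z
        assert np.allclose(ab, -ba)

    def test_index_mismatch_rejected(self):
        a = self.make([[0, 0.6], [0.6, 0]])
        b = CorrMatrix(z=np.zeros((2, 2)), index=("x", "y"), kind="roi")
        with pytest.raises(ValueError):
            difference_matrix([a], [b])


class TestCrossConsistency:
    def test_seed_map_matches_matrix_row_for_single_pixel_roi(self, rng):
        hbt = rng.normal(size=(80, 3, 3))
        m = movie_from_hbt(hbt)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z_img = seed_map(m, roi_at((3, 3), (0, 0)))
            cm = corr_matrix(m, spatial_downsample=1)
        k = cm.index.index((0, 0))
        for u, (r, c) in enumerate(cm.index):
            if u == k:
                continue
            assert z_img[r, c] == pytest.approx(cm.z[k, u], abs=1e-9)
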