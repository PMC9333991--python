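import numpy as np
import pytest

from mesomap.evoked import (BlockStack, block_average, cohens_d_map,
                            extract_blocks, group_threshold, incidence_map,
                            peak_map, response_metrics, t_map)
from mesomap.synthetic import electrical_paradigm

from conftest import movie_from_hbt


def make_stack(blocks, paradigm=None, fs=1.0, mask=None):
    blocks = np.asarray(blocks, dtype=float)
    paradigm = paradigm or electrical_paradigm(blocks.shape[0])
    if mask is None:
        mask = np.ones(blocks.shape[2:], bool)
    return BlockStack(blocks=blocks, block_onsets_s=paradigm.onsets_s(),
                      paradigm=paradigm, frame_rate=fs, mask=mask)


class TestExtract:
    def test_block_count_and_shape(self):
        par = electrical_paradigm(18)
        m = movie_from_hbt(np.zeros((900, 2, 2)), frame_rate=1.0)
        stack = extract_blocks(m, par)
        assert stack.n_blocks == 18
        assert stack.blocks.shape == (18, 50, 2, 2)

    def test_truncated_movie_drops_final_block(self):
        par = electrical_paradigm(18)
        m = movie_from_hbt(np.zeros((880, 2, 2)), frame_rate=1.0)
        with pytest.warns(UserWarning, match="truncated"):
            stack = extract_blocks(m, par)
        assert stack.n_blocks == 17

    def test_too_short_movie_yields_empty_stack(self):
        par = electrical_paradigm(2)
        m = movie_from_hbt(np.zeros((10, 2, 2)), frame_rate=1.0)
        with pytest.warns(UserWarning):
            stack = extract_blocks(m, par)
        assert stack.n_blocks == 0


class TestBlockAverage:
    def test_constant_movie_averages_to_zero(self):
        stack = make_stack(np.full((3, 50, 2, 2), 7.0))
        assert np.allclose(block_average(stack), 0.0)

    def test_single_block_is_itself_baseline_subtracted(self, rng):
        block = rng.normal(size=(1, 50, 2, 2))
        stack = make_stack(block)
        base = block[0, 0:4].mean(axis=0)  # [onset-5, onset-1) at 1 Hz, pre=5
        assert np.allclose(block_average(stack), block[0] - base)

    def test_planted_boxcar_amplitude_recovered(self, rng):
        par = electrical_paradigm(18)
        n = 18
        blocks = rng.normal(0, 1e-7, size=(n, 50, 3, 3))
        resp = np.zeros(50)
        resp[5:15] = 5e-6  # boxcar over the stim window
        blocks[:, :, 1, 1] += resp[None, :]
        avg = block_average(make_stack(blocks, par))
        peak = avg[5:15, 1, 1].mean()
        assert peak == pytest.approx(5e-6, abs=3 * 1e-7 / np.sqrt(18 * 10))


class TestPeakMap:
    def test_constant_average_passthrough(self):
        par = electrical_paradigm(1)
        avg = np.full((50, 2, 2), 4.0)
        assert np.allclose(peak_map(avg, par, 1.0), 4.0)

    def test_matches_brute_force_window(self, rng):
        par = electrical_paradigm(1)
        avg = rng.normal(size=(50, 3, 3))
        # offset = 15 s; window [13, 17) at 1 Hz -> frames 13..16
        expected = avg[13:17].mean(axis=0)
        assert np.allclose(peak_map(avg, par, 1.0), expected)

    def test_window_exceeding_block_rejected(self):
        par = electrical_paradigm(1)
        with pytest.raises(ValueError):
            peak_map(np.zeros((50, 2, 2)), par, 1.0, half_width_s=40.0)


class TestThresholdMetrics:
    def test_group_threshold_is_three_quarters_of_max(self, rng):
        mask = np.ones((4, 4), bool)
        maps = [np.zeros((4, 4)) for _ in range(3)]
        for m in maps:
            m[1, 1] = 8e-6
        assert group_threshold(maps, mask) == pytest.approx(6e-6)
        assert group_threshold(maps[::-1], mask) == pytest.approx(6e-6)

    def test_toy_three_pixel_metrics(self):
        peak = np.array([[5.0, 7.0, 9.0]])
        mask = np.ones((1, 3), bool)
        em = response_metrics(peak, 6.0, mask)
        assert em.area == 2
        assert em.magnitude == pytest.approx(9.0)

    def test_subthreshold_peak_missing_magnitude(self):
        peak = np.full((2, 2), 1.0)
        em = response_metrics(peak, 5.0, np.ones((2, 2), bool))
        assert em.area == 0 and np.isnan(em.magnitude)

    def test_uniform_at_threshold_counts_whole_mask(self):
        mask = np.ones((3, 3), bool)
        em = response_metrics(np.full((3, 3), 2.0), 2.0, mask)
        assert em.area == 9

    def test_region_mode_measures_attenuated_response(self):
        peak = np.zeros((3, 3))
        peak[1, 1] = 1.0  # 20% of an original 5.0 response
        region = np.zeros((3, 3), bool)
        region[1, 1] = True
        em = response_metrics(peak, 3.75, np.ones((3, 3), bool),
                              baseline_magnitude=5.0, region=region)
        assert em.area == 0
        assert em.magnitude_norm == pytest.approx(0.2)

    def test_metrics_monotone_in_threshold(self, rng):
        peak = rng.random((8, 8))
        mask = np.ones((8, 8), bool)
        areas = [response_metrics(peak, thr, mask).area
                 for thr in (0.8, 0.6, 0.4, 0.2)]
        assert areas == sorted(areas)

    def test_incidence_fractions(self):
        mask = np.ones((2, 2), bool)
        hot = np.array([[1.0, 0.0], [0.0, 0.0]])
        cold = np.zeros((2, 2))
        inc = incidence_map([hot, hot], 0.5, mask)
        assert inc[0, 0] == 1.0 and inc[1, 1] == 0.0
        inc2 = incidence_map([hot, cold], 0.5, mask)
        assert inc2[0, 0] == 0.5
        vals = np.unique(incidence_map([hot, cold, hot], 0.5, mask))
        assert np.all(np.isin(vals, [0, 1 / 3, 2 / 3, 1]))


class TestTMaps:
    def test_hand_computed_t(self):
        # block peak means [2, 4, 6]: t = mean/(sd/sqrt(n)) = 4/(2/sqrt(3))
        par = electrical_paradigm(3)
        blocks = np.zeros((3, 50, 1, 1))
        for i, v in enumerate((2.0, 4.0, 6.0)):
            blocks[i, 13:17, 0, 0] = v
        tm = t_map(make_stack(blocks, par))
        assert tm.t[0, 0] == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert tm.dof == 2

    def test_zero_variance_blocks_flagged(self):
        par = electrical_paradigm(4)
        blocks = np.zeros((4, 50, 1, 1))
        blocks[:, 13:17, 0, 0] = 1.0  # identical blocks -> sd 0
        tm = t_map(make_stack(blocks, par))
        assert tm.undefined[0, 0]
        assert tm.t[0, 0] == 0.0

    def test_cohens_d_identical_groups_zero(self, rng):
        from mesomap.evoked import TMap
        maps_a = [TMap(t=np.full((2, 2), 3.0), dof=17,
                       undefined=np.zeros((2, 2), bool)) for _ in range(3)]
        # identical groups but nonzero within-group spread
        for i, tm in enumerate(maps_a):
            tm.t = tm.t + i * 0.5
        maps_b = [TMap(t=m.t.copy(), dof=17,
                       undefined=np.zeros((2, 2), bool)) for m in maps_a]
        esm = cohens_d_map(maps_a, maps_b)
        assert np.allclose(esm.d[esm.inclusion_mask], 0.0)

    def test_cohens_d_shift_over_pooled_sd(self, rng):
        from mesomap.evoked import TMap

        def tmaps(vals):
            return [TMap(t=np.full((1, 1), v), dof=9,
                         undefined=np.zeros((1, 1), bool)) for v in vals]

        a_vals = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        delta = 1.5
        esm = cohens_d_map(tmaps(a_vals + delta), tmaps(a_vals))
        pooled_sd = a_vals.std(ddof=1)
        assert esm.d[0, 0] == pytest.approx(delta / pooled_sd, rel=1e-9)

    def test_cohens_d_matches_pooled_oracle(self, rng):
        from mesomap.evoked import TMap
        a = rng.normal(3, 1, size=(5, 2, 2))
        b = rng.normal(1, 1, size=(5, 2, 2))
        esm = cohens_d_map(
            [TMap(t=x, dof=9, undefined=np.zeros((2, 2), bool)) for x in a],
            [TMap(t=x, dof=9, undefined=np.zeros((2, 2), bool)) for x in b])
        i, j = 1, 0
        pooled = np.sqrt((4 * a[:, i, j].var(ddof=1)
                          + 4 * b[:, i, j].var(ddof=1)) / 8)
        expected = (a[:, i, j].mean() - b[:, i, j].mean()) / pooled
        if esm.inclusion_mask[i, j]:
            assert esm.d[i, j] == pytest.approx(expected, rel=1e-9)
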