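import numpy as np
import pytest
from scipy import stats

import dfckit as dk
from dfckit.stream import DFCStream, StreamConfig
from dfckit.linkindex import LinkIndex

from conftest import pearson_oracle


def _stream_from_frames(frames, w=10, step=10):
    frames = np.asarray(frames, dtype=float)
    n = {3: 3, 6: 4, 10: 5}[frames.shape[0]]
    starts = np.arange(frames.shape[1]) * step
    return DFCStream(frames, StreamConfig(w, step), starts, LinkIndex(n))


class TestDFCMatrix:
    def test_identical_frames_fully_similar(self):
        frames = np.tile(np.array([[0.1], [0.5], [-0.2]]), (1, 4))
        frames += 0  # identical columns
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        np.testing.assert_allclose(d.values, 1.0, atol=1e-12)

    def test_antilinear_frames_give_minus_one(self):
        frames = np.array([[0.1, 0.3], [0.2, 0.2], [0.3, 0.1]])
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        assert d.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_pairwise_pearson(self, rng):
        frames = rng.uniform(-1, 1, size=(6, 6))  # 4 regions, 6 frames
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        for a in range(6):
            for b in range(6):
                expect = 1.0 if a == b else pearson_oracle(
                    frames[:, a], frames[:, b])
                assert d.values[a, b] == pytest.approx(expect, abs=1e-10)

    def test_symmetric_unit_diagonal(self, small_stream):
        d = dk.compute_dfc_matrix(small_stream)
        np.testing.assert_allclose(d.values, d.values.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(d.values), 1.0)
        assert np.all(np.abs(d.values) <= 1.0)

    def test_constant_frame_is_named(self):
        frames = np.array([[0.1, 0.5, 0.5], [0.2, 0.5, 0.1], [0.3, 0.5, 0.2]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            dk.compute_dfc_matrix(_stream_from_frames(frames))


class TestSpeeds:
    def test_identical_consecutive_frames_zero_speed(self):
        frames = np.tile(np.array([[0.1], [0.4], [0.7]]), (1, 3))
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        s = dk.compute_speeds(d)
        np.testing.assert_allclose(s.speeds, 0.0, atol=1e-12)

    def test_antilinear_consecutive_frames_speed_two(self):
        frames = np.array([[0.1, 0.3], [0.2, 0.2], [0.3, 0.1]])
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        s = dk.compute_speeds(d)
        assert s.speeds[0] == pytest.approx(2.0, abs=1e-12)

    def test_frame_offset_indexing_matches_direct_lookup(self, rng):
        frames = rng.uniform(-1, 1, size=(10, 6))
        d = dk.compute_dfc_matrix(_stream_from_frames(frames))
        s = dk.compute_speeds(d, frame_offset=2)
        assert len(s) == 4
        for a in range(4):
            assert s.speeds[a] == pytest.approx(
                1.0 - d.values[a, a + 2], abs=1e-12)

    def test_speeds_bounded_on_random_streams(self, rng):
        for _ in range(10):
            frames = rng.uniform(-1, 1, size=(10, 8))
            d = dk.compute_dfc_matrix(_stream_from_frames(frames))
            s = dk.compute_speeds(d)
            assert np.all(s.speeds >= 0.0) and np.all(s.speeds <= 2.0)

    def test_offset_out_of_range_rejected(self, small_stream):
        d = dk.compute_dfc_matrix(small_stream)
        with pytest.raises(ValueError):
            dk.compute_speeds(d, frame_offset=d.n_frames)

    def test_oversampling_flagged(self, small_ts):
        smooth = dk.compute_dfc_stream(small_ts, dk.StreamConfig(30, 1))
        s = dk.compute_speeds(dk.compute_dfc_matrix(smooth), frame_offset=30)
        assert s.oversampled


class TestTypicalSpeedAndPooling:
    def test_median_of_odd_sample(self):
        s = dk.SpeedSample([0.2, 0.4, 0.6], window_size=10, frame_offset=1)
        assert dk.typical_speed(s, "median") == pytest.approx(0.4)

    def test_degenerate_distribution_both_methods(self):
        s = dk.SpeedSample(np.full(100, 0.73), window_size=10, frame_offset=1)
        assert dk.typical_speed(s, "median") == pytest.approx(0.73)
        # histogram mode is exact up to half a bin width
        mode = dk.typical_speed(s, "histogram_mode", bins=20)
        assert abs(mode - 0.73) <= 0.05

    def test_histogram_mode_finds_known_mode(self, rng):
        draws = np.clip(rng.normal(0.8, 0.1, size=1000), 0, 2)
        s = dk.SpeedSample(draws, window_size=10, frame_offset=1)
        mode = dk.typical_speed(s, "histogram_mode", bins=20)
        assert abs(mode - 0.8) <= 0.1  # within one bin of the true mode

    def test_empty_sample_rejected(self):
        s = dk.SpeedSample([], window_size=10, frame_offset=1)
        with pytest.raises(ValueError):
            dk.typical_speed(s)

    def test_pool_single_sample_is_identity(self):
        s = dk.SpeedSample([0.1, 0.2], window_size=10, frame_offset=1)
        pooled = dk.pool_speeds([s])
        np.testing.assert_array_equal(pooled.speeds, s.speeds)
        assert pooled.pooled_from == [10]

    def test_pool_concatenates_as_multiset(self):
        s1 = dk.SpeedSample([0.3, 0.1, 0.2], window_size=10, frame_offset=1)
        s2 = dk.SpeedSample([0.5, 0.4, 0.6, 0.7, 0.05],
                            window_size=12, frame_offset=1)
        pooled = dk.pool_speeds([s1, s2])
        assert len(pooled) == 8
        assert sorted(pooled.speeds) == sorted(
            list(s1.speeds) + list(s2.speeds))
        assert pooled.pooled_from == [10, 12]
        # pooled median equals the median of the sorted concatenation
        both = np.sort(np.concatenate([s1.speeds, s2.speeds]))
        assert dk.typical_speed(pooled) == pytest.approx(
            0.5 * (both[3] + both[4]))


class TestAgrestiCoull:
    def test_symmetric_center_at_half(self):
        lo, hi = dk.agresti_coull_interval(50, 100)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-12)

    def test_zero_successes_clipped_at_zero(self):
        lo, hi = dk.agresti_coull_interval(0, 40)
        assert lo == 0.0
        assert hi > 0.0

    def test_closed_form_half_width(self):
        z = 1.959963984540054  # standard-normal 97.5% quantile
        n_t = 100 + z * z
        p_t = (50 + z * z / 2) / n_t
        hw = z * np.sqrt(p_t * (1 - p_t) / n_t)
        lo, hi = dk.agresti_coull_interval(50, 100)
        assert hi - lo == pytest.approx(2 * hw, abs=1e-9)

    @pytest.mark.parametrize("x,n", [(0, 10), (3, 10), (10, 10), (77, 200)])
    def test_matches_statsmodels_oracle(self, x, n):
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = dk.agresti_coull_interval(x, n)
        slo, shi = proportion_confint(x, n, alpha=0.05,
                                      method="agresti_coull")
        assert lo == pytest.approx(max(0.0, slo), abs=1e-10)
        assert hi == pytest.approx(min(1.0, shi), abs=1e-10)


class TestSpeedHistogram:
    def test_probabilities_normalised_with_cis(self, rng):
        s = dk.SpeedSample(rng.uniform(0, 2, 500), window_size=10,
                           frame_offset=1)
        h = dk.build_speed_histogram(s)
        assert h.bin_probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(h.ci_low <= h.bin_probabilities + 1e-12)
        assert np.all(h.bin_probabilities <= h.ci_high + 1e-12)
        assert np.all(h.ci_low >= 0) and np.all(h.ci_high <= 1)

    def test_out_of_range_speeds_flagged(self):
        s = dk.SpeedSample([0.5, 0.6, 3.0], window_size=10, frame_offset=1)
        with pytest.warns(UserWarning, match="outside bin range"):
            h = dk.build_speed_histogram(s)
        assert h.n_overflow == 1
        assert h.n_observations == 2

    def test_empirical_vs_shuffled_speeds_indistinguishable_when_stationary(self):
        # frames of a stationary white fixture are exchangeable, so frame
        # shuffling must leave the speed distribution unchanged (KS test)
        ts = dk.gen_stationary_gaussian(6, 1200, seed=77)
        stream = dk.compute_dfc_stream(ts, dk.StreamConfig(30, 30))
        d = dk.compute_dfc_matrix(stream)
        emp = dk.compute_speeds(d).speeds
        shuffled = dk.time_shuffle_stream(stream, seed=4)
        sur = dk.compute_speeds(dk.compute_dfc_matrix(shuffled)).speeds
        _, p = stats.ks_2samp(emp, sur)
        assert p > 0.05
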