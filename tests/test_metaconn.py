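import numpy as np
import pytest
from scipy import stats

import dfckit as dk
from dfckit.linkindex import LinkIndex
from dfckit.metaconn import MCMatrix
from dfckit.stream import DFCStream, StreamConfig

from conftest import pearson_oracle


def _mc_from_compact(compact, n):
    return MCMatrix(np.asarray(compact, float), n, StreamConfig(10, 1))


@pytest.fixture
def random_mc(rng):
    n = 5
    l = 10
    a = rng.uniform(-1, 1, size=(l, l))
    compact = (a + a.T) / 2
    np.fill_diagonal(compact, 1.0)
    return _mc_from_compact(compact, n)


@pytest.fixture
def mc_stream(rng):
    """4-region, 30-frame random stream."""
    frames = rng.uniform(-1, 1, size=(6, 30))
    return DFCStream(frames, StreamConfig(10, 1), np.arange(30), LinkIndex(4))


class TestComputeMC:
    def test_identical_link_rows_give_all_ones(self):
        row = np.linspace(-0.5, 0.5, 20)
        frames = np.tile(row, (6, 1))
        stream = DFCStream(frames, StreamConfig(10, 1), np.arange(20),
                           LinkIndex(4))
        mc = dk.compute_mc(stream)
        np.testing.assert_allclose(mc.compact, 1.0, atol=1e-12)

    def test_matches_bruteforce_double_loop(self, mc_stream):
        mc = dk.compute_mc(mc_stream)
        frames = mc_stream.frames
        for a in range(6):
            for b in range(a + 1, 6):
                expect = pearson_oracle(frames[a], frames[b])
                assert mc.compact[a, b] == pytest.approx(expect, abs=1e-10)
        np.testing.assert_array_equal(np.diag(mc.compact), 1.0)

    def test_equals_row_correlation_of_vector_stream(self, smooth_stream):
        mc = dk.compute_mc(smooth_stream)
        np.testing.assert_allclose(
            mc.compact, np.corrcoef(smooth_stream.frames), atol=1e-12)

    def test_constant_link_zeroed_with_warning(self, mc_stream):
        frames = mc_stream.frames.copy()
        frames[2] = 0.4
        stream = DFCStream(frames, StreamConfig(10, 1), np.arange(30),
                           LinkIndex(4))
        with pytest.warns(UserWarning, match=r"\[2\]"):
            mc = dk.compute_mc(stream)
        assert mc.compact[2, 2] == 1.0
        assert np.all(mc.compact[2, [0, 1, 3, 4, 5]] == 0.0)
        assert np.all(mc.compact[[0, 1, 3, 4, 5], 2] == 0.0)

    def test_too_few_frames_rejected(self, rng):
        frames = rng.uniform(-1, 1, size=(6, 2))
        stream = DFCStream(frames, StreamConfig(10, 1), np.arange(2),
                           LinkIndex(4))
        with pytest.raises(ValueError, match="3 frames"):
            dk.compute_mc(stream)

    def test_permutation_equivariance(self, rng):
        # relabeling regions permutes MC by the induced link permutation
        ts = dk.gen_stationary_gaussian(5, 300, seed=9)
        perm = rng.permutation(5)
        ts_p = dk.TimeSeriesMatrix(ts.values[:, perm])
        cfg = StreamConfig(20, 1)
        mc = dk.compute_mc(dk.compute_dfc_stream(ts, cfg)).compact
        mc_p = dk.compute_mc(dk.compute_dfc_stream(ts_p, cfg)).compact
        idx = LinkIndex(5)
        # link m of the permuted data joins original regions perm[i], perm[j]
        link_map = np.array([
            idx.ordinal_of(perm[i], perm[j])
            for m in range(idx.n_links)
            for (i, j) in [idx.pair_of(m)]
        ])
        np.testing.assert_allclose(
            mc_p, mc[np.ix_(link_map, link_map)], atol=1e-10)

    def test_reproducible_across_generator_seeds(self):
        # two independent realisations of the same planted structure give
        # strongly correlated MCs (the group-averageability rationale)
        mats = []
        for seed in (21, 22):
            fix = dk.gen_planted_mc_modules(n_samples=4000, seed=seed)
            stream = dk.compute_dfc_stream(fix.timeseries,
                                           StreamConfig(20, 1))
            mats.append(dk.compute_mc(stream).compact)
        iu = np.triu_indices(mats[0].shape[0], k=1)
        r = np.corrcoef(mats[0][iu], mats[1][iu])[0, 1]
        assert r > 0.8


class TestExpandMC:
    def test_n3_expansion_shape(self, rng):
        a = rng.uniform(-1, 1, (3, 3))
        compact = (a + a.T) / 2
        np.fill_diagonal(compact, 1.0)
        big = dk.expand_mc(_mc_from_compact(compact, 3))
        assert big.shape == (6, 6)

    def test_eightfold_degeneracy_exact(self, random_mc, rng):
        big = dk.expand_mc(random_mc)
        idx = random_mc.link_index
        for _ in range(20):
            m1, m2 = rng.integers(0, idx.n_links, size=2)
            i, j = idx.pair_of(int(m1))
            k, l = idx.pair_of(int(m2))
            val = random_mc.compact[m1, m2]
            d = idx.directed_ordinal_of
            positions = [
                (d(i, j), d(k, l)), (d(j, i), d(k, l)),
                (d(i, j), d(l, k)), (d(j, i), d(l, k)),
                (d(k, l), d(i, j)), (d(k, l), d(j, i)),
                (d(l, k), d(i, j)), (d(l, k), d(j, i)),
            ]
            assert len({p for p in positions}) == (4 if m1 == m2 else 8)
            for (a, b) in positions:
                assert big[a, b] == val

    def test_memory_cap_refusal(self, random_mc):
        with pytest.raises(MemoryError, match="compact-mode"):
            dk.expand_mc(random_mc, max_bytes=100)


class TestTrimerStrengths:
    def test_all_ones_mc_gives_pair_count(self):
        for n in (4, 5, 7):
            l = n * (n - 1) // 2
            mc = _mc_from_compact(np.ones((l, l)), n)
            ms = dk.trimer_strengths(mc)
            np.testing.assert_allclose(
                ms.values, (n - 1) * (n - 2) / 2, atol=1e-12)

    def test_matches_bruteforce_triple_loop(self, random_mc):
        idx = random_mc.link_index
        n = idx.n_regions
        ms = dk.trimer_strengths(random_mc)
        for i in range(n):
            total = 0.0
            others = [k for k in range(n) if k != i]
            for a, k in enumerate(others):
                for l in others[a + 1:]:
                    total += random_mc.compact[
                        idx.ordinal_of(i, k), idx.ordinal_of(i, l)]
            assert ms.values[i] == pytest.approx(total, abs=1e-10)

    def test_compact_and_expanded_agree(self, random_mc):
        # recompute strengths from the expanded view: sum over ordered pairs
        # of directed links rooted at i, divided by the 4-fold degeneracy
        big = dk.expand_mc(random_mc)
        idx = random_mc.link_index
        n = idx.n_regions
        ms = dk.trimer_strengths(random_mc)
        for i in range(n):
            rooted = [idx.directed_ordinal_of(i, k)
                      for k in range(n) if k != i]
            sub = big[np.ix_(rooted, rooted)]
            recomputed = (sub.sum() - np.trace(sub)) / 2.0
            assert ms.values[i] == pytest.approx(recomputed, abs=1e-10)

    def test_star_restriction_equals_unrestricted_when_offstar_zero(self):
        n = 5
        idx = LinkIndex(n)
        l = idx.n_links
        compact = np.zeros((l, l))
        np.fill_diagonal(compact, 1.0)
        star = idx.incident_links(0)
        for a in star:
            for b in star:
                if a != b:
                    compact[a, b] = 0.6
        mc = _mc_from_compact(compact, n)
        full = dk.trimer_strengths(mc)
        restricted = dk.trimer_strengths(mc, restrict_links=star)
        assert restricted.values[0] == pytest.approx(full.values[0])

    def test_empty_restriction_warns_all_zero(self, random_mc):
        with pytest.warns(UserWarning, match="empty"):
            ms = dk.trimer_strengths(random_mc,
                                     restrict_links=np.array([], dtype=int))
        np.testing.assert_array_equal(ms.values, 0.0)

    def test_out_of_range_restriction_rejected(self, random_mc):
        with pytest.raises(IndexError):
            dk.trimer_strengths(random_mc, restrict_links=[99])


class TestEFC:
    def test_duplicated_regions_share_product_series(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        ts = dk.TimeSeriesMatrix(np.column_stack([x, x, x, y]))
        efc = dk.compute_efc(ts)
        idx = LinkIndex(4)
        # links (0,1) and (0,2) are both z0*z0 up to z-scoring: identical
        m1, m2 = idx.ordinal_of(0, 1), idx.ordinal_of(0, 2)
        assert efc[m1, m2] == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_unit_diagonal(self, small_ts):
        efc = dk.compute_efc(small_ts)
        np.testing.assert_allclose(efc, efc.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(efc), 1.0)

    def test_constant_region_rejected(self):
        vals = np.column_stack([np.arange(20.0), np.full(20, 1.0)])
        with pytest.raises(ValueError, match="constant"):
            dk.compute_efc(dk.TimeSeriesMatrix(vals))

    def test_positively_rank_correlated_with_mc(self):
        fix = dk.gen_planted_mc_modules(n_regions=6, n_samples=2000, seed=13)
        stream = dk.compute_dfc_stream(fix.timeseries, StreamConfig(20, 1))
        mc = dk.compute_mc(stream).compact
        efc = dk.compute_efc(fix.timeseries)
        iu = np.triu_indices(mc.shape[0], k=1)
        rho, _ = stats.spearmanr(mc[iu], efc[iu])
        assert rho > 0
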