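"""Insulation scores, TAD calls, sharing rules and metaplots."""

import numpy as np
import pytest

from rhythmhic.domains import (InsulationTrack, TAD, call_tads,
                               find_boundaries, insulation_score,
                               point_metaplot, shared_tads, tad_metaplot)
from rhythmhic.genome import GenomicInterval
from rhythmhic.matrix import ContactMatrix


def _mat(M, bin_size=50_000):
    return ContactMatrix("chr1", bin_size, np.asarray(M, float))


class TestInsulation:
    def test_constant_field(self):
        M = np.full((12, 12), 4.0)
        tr = insulation_score(_mat(M), 100_000)  # w = 2
        interior = tr.score[2:-2]
        assert np.allclose(interior, 4.0)
        assert np.isnan(tr.score[:2]).all() and np.isnan(tr.score[-2:]).all()

    def test_matches_bruteforce_window_means(self, rng):
        A = rng.random((12, 12))
        A = (A + A.T) / 2
        tr = insulation_score(_mat(A), 100_000)
        w = 2
        for i in range(w, 12 - w):
            expect = A[i - w:i, i + 1:i + w + 1].mean()
            assert np.isclose(tr.score[i], expect)

    def test_block_junction_is_global_minimum(self):
        n = 20
        M = np.full((n, n), 0.1)
        M[:10, :10] = 5.0
        M[10:, 10:] = 5.0
        tr = insulation_score(_mat(M), 150_000)  # w = 3
        assert np.nanargmin(tr.score) in (9, 10)

    def test_linearity_in_matrix(self, rng):
        A = rng.random((14, 14))
        A = (A + A.T) / 2
        t1 = insulation_score(_mat(A), 100_000)
        t2 = insulation_score(_mat(3 * A), 100_000)
        m = np.isfinite(t1.score)
        assert np.allclose(t2.score[m], 3 * t1.score[m])

    def test_window_larger_than_chromosome_errors(self):
        with pytest.raises(ValueError):
            insulation_score(_mat(np.ones((4, 4))), 200_000)


class TestCallTads:
    def test_no_bin_below_threshold_gives_no_tads(self):
        M = np.full((20, 20), 2.0)
        tr = insulation_score(_mat(M), 100_000)
        assert call_tads(tr, threshold=1.0) == []

    def test_planted_boundaries_one_mb_apart(self):
        # two block junctions 1 Mb apart -> exactly one TAD between them
        n = 40
        M = np.full((n, n), 0.2)
        for s, e in ((0, 10), (10, 30), (30, 40)):
            M[s:e, s:e] = 5.0
        tr = insulation_score(_mat(M), 100_000)
        tads = call_tads(tr, threshold=float(np.nanmean(tr.score)))
        assert len(tads) == 1
        assert tads[0].length == 1_000_000

    def test_masked_gap_blocks_tads(self):
        n = 40
        M = np.full((n, n), 0.2)
        for s, e in ((0, 10), (10, 30), (30, 40)):
            M[s:e, s:e] = 5.0
        tr = insulation_score(_mat(M), 100_000)
        tr.score[20] = np.nan  # gap inside the middle domain
        tads = call_tads(tr, threshold=float(np.nanmean(tr.score)))
        assert tads == []

    def test_appending_masked_bins_leaves_calls_unchanged(self):
        n = 40
        M = np.full((n, n), 0.2)
        for s, e in ((0, 10), (10, 30), (30, 40)):
            M[s:e, s:e] = 5.0
        tr = insulation_score(_mat(M), 100_000)
        thr = float(np.nanmean(tr.score))
        base = [(t.interval.start, t.interval.end) for t in call_tads(tr, thr)]
        padded = InsulationTrack(tr.chrom, tr.bin_size, tr.window_bp,
                                 np.concatenate([tr.score, [np.nan] * 5]),
                                 np.concatenate([tr.normalized_score, [np.nan] * 5]))
        assert [(t.interval.start, t.interval.end)
                for t in call_tads(padded, thr)] == base


class TestSharedTads:
    def _tad(self, start, end):
        return TAD(GenomicInterval("chr1", start, end))

    def test_identical_sets_all_shared(self):
        a = [self._tad(0, 500_000), self._tad(500_000, 1_000_000)]
        res = shared_tads(a, a)
        assert res.n_shared == 2 and not res.unshared

    def test_exactly_80_percent_not_shared(self):
        x = [self._tad(0, 1_000_000)]
        y = [self._tad(200_000, 1_000_000)]  # overlap exactly 0.80
        res = shared_tads(x, y)
        assert res.n_shared == 0

    def test_85_percent_shared(self):
        x = [self._tad(0, 1_000_000)]
        y = [self._tad(150_000, 1_000_000)]  # overlap fraction 0.85
        res = shared_tads(x, y)
        assert res.n_shared == 1
        assert np.isclose(res.pairs[0][2], 0.85)


class TestTadMetaplot:
    def test_flat_oe_gives_unity_grid(self):
        oe = np.ones((60, 60))
        tads = [TAD(GenomicInterval("chr1", 1_000_000, 1_500_000))]
        res = tad_metaplot(oe, tads, bin_size=50_000)
        assert np.allclose(res.grid[np.isfinite(res.grid)], 1.0)
        assert res.grid.shape == (15, 15)

    def test_single_tad_matches_rebinning_oracle(self, rng):
        oe = rng.random((60, 60))
        oe = (oe + oe.T) / 2
        tads = [TAD(GenomicInterval("chr1", 1_000_000, 1_500_000))]  # 10 bins
        res = tad_metaplot(oe, tads, bin_size=50_000, flank_bins=5, n_core=5)
        # brute-force oracle: fine-grained subdivision average per grid cell
        b0, b1 = 20, 30
        f = 5.0
        lo = 15
        sub = oe[lo:40, lo:40]
        cuts = np.concatenate([
            np.linspace(0, f, 6)[:-1], np.linspace(f, f + 10, 6)[:-1],
            np.linspace(f + 10, 2 * f + 10, 6)]) + (b0 - f - lo)
        K = 400  # subsamples per axis cell
        grid = np.zeros((15, 15))
        for gi in range(15):
            xs = np.linspace(cuts[gi], cuts[gi + 1], K, endpoint=False) \
                + (cuts[gi + 1] - cuts[gi]) / (2 * K)
            for gj in range(15):
                ys = np.linspace(cuts[gj], cuts[gj + 1], K, endpoint=False) \
                    + (cuts[gj + 1] - cuts[gj]) / (2 * K)
                grid[gi, gj] = sub[np.floor(xs).astype(int)][:,
                                   np.floor(ys).astype(int)].mean()
        assert np.allclose(res.grid, grid, atol=2e-3)

    def test_short_tad_skipped(self):
        oe = np.ones((60, 60))
        tads = [TAD(GenomicInterval("chr1", 0, 100_000))]  # 2 bins < n_core
        res = tad_metaplot(oe, tads, bin_size=50_000)
        assert res.n_features == 0 and res.n_skipped == 1

    def test_planted_tads_enriched_in_core(self, default_truth):
        from rhythmhic.matrix import balance, oe_transform
        from rhythmhic.simulate import simulate_hic

        cfg = default_truth.config
        m = simulate_hic(default_truth, 0, 1, depth=3000, chrom="chr1",
                         bin_size=cfg.bin_size_tad)
        oe = oe_transform(balance(m))
        tads = [TAD(GenomicInterval("chr1", s, e))
                for s, e in default_truth.tads["chr1"]]
        res = tad_metaplot(oe, tads, bin_size=cfg.bin_size_tad)
        core = res.grid[5:10, 5:10]
        corners = np.concatenate([res.grid[:3, 12:].ravel(),
                                  res.grid[12:, :3].ravel()])
        # within-domain contacts clearly exceed the cross-boundary corners;
        # the per-diagonal expected model absorbs part of the domain factor
        # because the simulated TADs tile the chromosome, capping the ratio
        assert np.nanmean(core) / np.nanmean(corners) >= 1.3

    def test_random_intervals_on_null_simulation_flat(self):
        from rhythmhic.matrix import balance, oe_transform
        from rhythmhic.simulate import SimConfig, simulate_hic, simulate_truth

        cfg = SimConfig(seed=11, n_chrom=1, chrom_length=20_000_000,
                        compartment_contrast=0.0, tad_enrichment=1.0,
                        n_genes=40, n_enhancers=40, hic_depth=20000)
        truth = simulate_truth(cfg)
        m = simulate_hic(truth, 0, 1, bin_size=cfg.bin_size_tad)
        oe = oe_transform(balance(m))
        rng = np.random.default_rng(4)
        tads = []
        for _ in range(120):
            s = int(rng.integers(0, 300)) * 50_000
            size = int(rng.integers(6, 16)) * 50_000
            if s + size <= 20_000_000:
                tads.append(TAD(GenomicInterval("chr1", s, s + size)))
        res = tad_metaplot(oe, tads, bin_size=50_000)
        finite = res.grid[np.isfinite(res.grid)]
        assert np.all(np.abs(finite - 1.0) <= 0.1)


class TestPointMetaplot:
    def test_flat_oe_gives_unity(self):
        oe = np.ones((30, 30))
        res = point_metaplot(oe, [15], bin_size=50_000, window_bins=3)
        assert np.allclose(res.grid, 1.0)

    def test_single_point_identity(self, rng):
        oe = rng.random((30, 30))
        res = point_metaplot(oe, [10], bin_size=50_000, window_bins=1)
        assert np.array_equal(res.grid, oe[9:12, 9:12])

    def test_edge_point_skipped(self):
        oe = np.ones((30, 30))
        res = point_metaplot(oe, [1], bin_size=50_000, window_bins=3)
        assert res.n_features == 0 and res.n_skipped == 1

    def test_boundary_points_show_insulation_quadrants(self, default_truth):
        from rhythmhic.matrix import balance, oe_transform
        from rhythmhic.simulate import simulate_hic

        cfg = default_truth.config
        m = simulate_hic(default_truth, 0, 1, depth=3000, chrom="chr1",
                         bin_size=cfg.bin_size_tad)
        oe = oe_transform(balance(m))
        pts = [int(b) // cfg.bin_size_tad
               for b in default_truth.tad_boundaries("chr1")]
        res = point_metaplot(oe, pts, bin_size=cfg.bin_size_tad, window_bins=4)
        k = 4
        ul = np.nanmean(res.grid[:k, :k])       # upstream domain
        lr = np.nanmean(res.grid[k + 1:, k + 1:])  # downstream domain
        off = np.nanmean(res.grid[:k, k + 1:])  # cross-boundary
        assert (ul + lr) / 2 > off
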