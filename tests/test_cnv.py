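import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfevo.cnv import (
    BinCounts,
    BinGrid,
    CBSParams,
    cbs_segment,
    count_reads_in_bins,
    exome_cn_ratio,
    merge_levels,
    normalize,
)
from cfevo.errors import InvalidArgument


class TestBinGrid:
    def test_uniform_tiling_truncates_last_bin(self):
        g = BinGrid.uniform({"chr1": 250}, 100)
        assert list(g.start) == [0, 100, 200]
        assert list(g.end) == [100, 200, 250]

    @pytest.mark.parametrize(
        "chrom,start,end",
        [
            (["chr1", "chr1"], [0, 50], [100, 150]),  # overlap
            (["chr1", "chr1"], [100, 0], [200, 100]),  # unsorted
            (["chr1"], [10], [10]),  # empty interval
        ],
    )
    def test_invalid_grids_rejected(self, chrom, start, end):
        with pytest.raises(InvalidArgument):
            BinGrid(np.array(chrom, dtype=object), np.array(start), np.array(end))


class TestCountReads:
    def test_half_open_boundaries(self, grid_small):
        # a read at a bin's start belongs to it; at its end, to the next bin
        counts = count_reads_in_bins([("chr1", 100), ("chr1", 200)], grid_small)
        assert counts.raw[1] == 1  # pos 100 = start of bin 1
        assert counts.raw[2] == 1  # pos 200 = end of bin 1 = start of bin 2
        assert counts.n_dropped_reads == 0

    def test_unknown_chromosome_dropped_with_warning(self, grid_small):
        with pytest.warns(UserWarning):
            counts = count_reads_in_bins([("chrUn", 5), ("chr1", 5)], grid_small)
        assert counts.n_dropped_reads == 1
        assert counts.raw.sum() == 1

    def test_uniform_positions_multinomial(self, grid_small):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 1000, size=10_000)
        counts = count_reads_in_bins([("chr1", int(p)) for p in pos], grid_small)
        # each of 10 bins expects 1000, sd = sqrt(n p (1-p)) = 30
        assert np.all(np.abs(counts.raw - 1000) < 4 * 30)
        assert counts.raw.sum() == 10_000


class TestNormalize:
    def test_uniform_counts(self, grid_small):
        c = normalize(BinCounts(grid=grid_small, raw=np.full(10, 7)))
        assert np.allclose(c.ratio, 1.0)
        assert np.allclose(c.log2ratio, 0.0)

    def test_arithmetic(self):
        g = BinGrid.uniform({"chr1": 300}, 100)
        c = normalize(BinCounts(grid=g, raw=np.array([2, 4, 6])))
        assert np.allclose(c.ratio, [0.5, 1.0, 1.5])

    def test_zero_bin_floored_and_flagged(self):
        g = BinGrid.uniform({"chr1": 300}, 100)
        c = normalize(BinCounts(grid=g, raw=np.array([0, 4, 8])))
        floor = 1.0 / (2 * 4.0)
        assert c.zero_flag[0] and not c.zero_flag[1]
        assert c.log2ratio[0] == pytest.approx(np.log2(floor))
        assert c.ratio.mean() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self, grid_small):
        with pytest.raises(InvalidArgument):
            normalize(BinCounts(grid=grid_small, raw=np.zeros(10, dtype=int)))

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_ratio_conserved(self, grid_small, seed):
        raw = np.random.default_rng(seed).poisson(30, size=10)
        c = normalize(BinCounts(grid=grid_small, raw=raw))
        assert c.ratio.mean() == pytest.approx(1.0, abs=1e-9)


class TestCBS:
    def test_constant_signal_single_segment(self, grid_1000):
        c = normalize(BinCounts(grid=grid_1000, raw=np.full(1000, 50)))
        assert cbs_segment(c, CBSParams(seed=0)).n_segments == 1

    def test_planted_step_recovered(self, grid_1000):
        rng = np.random.default_rng(5)
        x = np.ones(1000)
        x[500:] += 1.0
        raw = np.maximum((x + rng.normal(0, 0.1, 1000)) * 50, 0).astype(int)
        prof = cbs_segment(normalize(BinCounts(grid=grid_1000, raw=raw)), CBSParams(seed=5))
        assert prof.n_segments == 2
        assert abs(int(prof.segments.loc[1, "start_bin"]) - 500) <= 1

    def test_partition_and_reconstruction(self, grid_1000):
        rng = np.random.default_rng(2)
        x = np.ones(1000)
        x[300:700] += 0.8
        raw = np.maximum((x + rng.normal(0, 0.1, 1000)) * 50, 0).astype(int)
        c = normalize(BinCounts(grid=grid_1000, raw=raw))
        prof = cbs_segment(c, CBSParams(seed=2))
        # segments partition the bins exactly
        covered = np.zeros(1000, dtype=int)
        for row in prof.segments.itertuples():
            covered[row.start_bin : row.end_bin + 1] += 1
            member_mean = c.ratio[row.start_bin : row.end_bin + 1].mean()
            assert row.mean_ratio == pytest.approx(member_mean)
            assert np.all(prof.per_bin_segvalue[row.start_bin : row.end_bin + 1] == row.mean_ratio)
        assert np.all(covered == 1)

    def test_alpha_monotonicity(self, grid_1000):
        rng = np.random.default_rng(3)
        x = np.ones(1000)
        x[500:] += 1.0
        raw = np.maximum((x + rng.normal(0, 0.1, 1000)) * 50, 0).astype(int)
        c = normalize(BinCounts(grid=grid_1000, raw=raw))
        n_strict = cbs_segment(c, CBSParams(alpha=1e-12, n_permutations=2000, seed=3)).n_segments
        n_loose = cbs_segment(c, CBSParams(alpha=0.01, n_permutations=2000, seed=3)).n_segments
        assert n_strict <= n_loose

    def test_too_few_bins_single_segment(self):
        g = BinGrid.uniform({"chr1": 300}, 100)
        c = normalize(BinCounts(grid=g, raw=np.array([10, 50, 90])))
        prof = cbs_segment(c, CBSParams(min_seg_bins=2, seed=0))
        assert prof.n_segments <= 2  # cannot split below min width


class TestMergeLevels:
    def _counts(self, grid, values, seed=0):
        rng = np.random.default_rng(seed)
        raw = np.maximum((values + rng.normal(0, 0.05, len(values))) * 100, 0).astype(int)
        return normalize(BinCounts(grid=grid, raw=raw))

    def test_identical_adjacent_segments_merged(self, grid_small):
        c = normalize(BinCounts(grid=grid_small, raw=np.full(10, 40)))
        from .conftest import make_profile

        prof = make_profile(grid_small, c.ratio, breaks_by_chrom={"chr1": [5]})
        assert prof.n_segments == 2
        merged = merge_levels(prof, c)
        assert merged.n_segments == 1

    def test_separated_segments_not_merged(self):
        g = BinGrid.uniform({"chr1": 100 * 100}, 100)
        vals = np.concatenate([np.full(50, 0.5), np.full(50, 1.5)])
        c = self._counts(g, vals, seed=1)
        from .conftest import make_profile

        prof = make_profile(g, c.ratio, breaks_by_chrom={"chr1": [50]})
        merged = merge_levels(prof, c)
        assert merged.n_segments == 2

    def test_idempotent_and_never_grows(self, grid_1000):
        rng = np.random.default_rng(7)
        x = np.ones(1000)
        x[400:] += 0.6
        raw = np.maximum((x + rng.normal(0, 0.1, 1000)) * 50, 0).astype(int)
        c = normalize(BinCounts(grid=grid_1000, raw=raw))
        prof = cbs_segment(c, CBSParams(seed=7))
        m1 = merge_levels(prof, c)
        m2 = merge_levels(m1, c)
        assert m1.n_segments <= prof.n_segments
        assert m2.n_segments == m1.n_segments
        assert np.array_equal(m2.per_bin_segvalue, m1.per_bin_segvalue)

    def test_borderline_merge_matches_direct_ranksum(self):
        # decision on a borderline pair equals the direct two-sided test
        g = BinGrid.uniform({"chr1": 60 * 100}, 100)
        rng = np.random.default_rng(11)
        vals = np.concatenate([np.full(30, 1.0), np.full(30, 1.02)])
        raw = np.maximum((vals + rng.normal(0, 0.05, 60)) * 100, 0).astype(int)
        c = normalize(BinCounts(grid=g, raw=raw))
        from .conftest import make_profile

        prof = make_profile(g, c.ratio, breaks_by_chrom={"chr1": [30]})
        p = stats.mannwhitneyu(c.ratio[:30], c.ratio[30:], alternative="two-sided").pvalue
        merged = merge_levels(prof, c, merge_p_threshold=0.05)
        assert (merged.n_segments == 1) == (p >= 0.05)


class TestExomeRatio:
    def test_identical_depths_zero(self):
        t = np.array([100.0, 200.0, 300.0])
        log2, excl = exome_cn_ratio(t, t)
        assert np.allclose(log2, 0.0)
        assert not excl.any()

    def test_doubled_block_unit_log_ratio(self):
        n = np.full(40, 100.0)
        t = n.copy()
        t[:8] *= 2  # minority block doubled
        log2, _ = exome_cn_ratio(t, n)
        assert np.allclose(log2[:8], 1.0, atol=1e-6)
        assert np.allclose(log2[8:], 0.0, atol=1e-6)

    def test_single_target_centered_to_zero(self):
        log2, _ = exome_cn_ratio(np.array([55.0]), np.array([70.0]))
        assert log2[0] == pytest.approx(0.0)

    def test_zero_normal_target_excluded(self):
        log2, excl = exome_cn_ratio(np.array([10.0, 20.0]), np.array([0.0, 20.0]))
        assert excl[0] and not excl[1]
        assert np.isnan(log2[0])
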