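import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfevo.cna import (
    CNACall,
    PloidyThresholds,
    annotate_genes,
    call_cnas,
    classify_ploidy,
    cna_burden,
    mutation_concordance,
    neutral_level,
    plasma_tissue_correlation,
)
from cfevo.cnv import BinGrid
from cfevo.errors import GridMismatch

from .conftest import make_profile


@pytest.fixture
def grid():
    return BinGrid.uniform({"chr1": 220_000 * 100}, 220_000)


class TestNeutralLevel:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (np.ones(100), 1.0),
            (np.concatenate([np.full(60, 1.0), np.full(40, 1.5)]), 1.0),
            (np.concatenate([np.full(50, 0.8), np.full(50, 1.2)]), 1.0),
        ],
    )
    def test_median_of_bins(self, grid, values, expected):
        assert neutral_level(make_profile(grid, values)) == pytest.approx(expected)


class TestCallCnas:
    def test_flat_profile_empty(self, grid):
        assert call_cnas(make_profile(grid, np.ones(100)), 1.0) == []

    def test_amplified_run_length(self, grid):
        vals = np.ones(100)
        vals[10:20] = 1.5
        calls = call_cnas(make_profile(grid, vals), 1.0)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "amplification"
        assert c.n_bins == 10
        # length = end of bin 19 minus start of bin 10 = 10 bins of 220 kb
        assert c.length_bp == 2_200_000
        assert c.start_bp == 10 * 220_000

    def test_two_runs_two_calls(self, grid):
        vals = np.ones(100)
        vals[5:10] = 0.6
        vals[50:60] = 1.4
        calls = call_cnas(make_profile(grid, vals), 1.0)
        assert [c.direction for c in calls] == ["deletion", "amplification"]

    def test_runs_do_not_cross_chromosomes(self):
        g = BinGrid.uniform({"chrA": 220_000 * 5, "chrB": 220_000 * 5}, 220_000)
        vals = np.full(10, 1.5)  # both chromosomes entirely amplified
        calls = call_cnas(make_profile(g, vals), 1.0)
        assert len(calls) == 2
        assert {c.chrom for c in calls} == {"chrA", "chrB"}


class TestCnaBurden:
    def _calls(self, deviations):
        return [
            CNACall("chr1", 0, 220_000, "amplification", 1.0 + d, 1) for d in deviations
        ]

    def test_baseline_zero_counts_all(self):
        assert cna_burden(self._calls([0.02, 0.05, 0.4]), 0.0) == 3

    def test_baseline_threshold(self):
        assert cna_burden(self._calls([0.02, 0.05, 0.4]), 0.03) == 2

    def test_empty(self):
        assert cna_burden([], 0.03) == 0


class TestClassifyPloidy:
    def _profile(self, n_segments, deviation, grid_bins=1000, big_segment=False):
        """Profile with n_segments segments; the first deviates by ``deviation``
        and spans 50 bins (11 Mb) when big_segment, else 2 bins (0.44 Mb)."""
        g = BinGrid.uniform({"chr1": 220_000 * grid_bins}, 220_000)
        vals = np.ones(grid_bins)
        if n_segments == 1:
            vals[:] = 1.0 + deviation
            return make_profile(g, vals, breaks_by_chrom={"chr1": []})
        dev_bins = 50 if big_segment else 2
        vals[:dev_bins] = 1.0 + deviation
        interior = np.linspace(dev_bins, grid_bins, n_segments).astype(int)[1:-1]
        breaks = [dev_bins] + interior.tolist()
        assert len(set(breaks)) == n_segments - 1
        return make_profile(g, vals, breaks_by_chrom={"chr1": breaks})

    def test_single_flat_segment_diploid(self):
        assert classify_ploidy(self._profile(1, 0.0)).label == "diploid"

    def test_many_segments_with_deviation_aneuploid(self):
        call = classify_ploidy(self._profile(50, 0.05))
        assert call.label == "aneuploid"
        assert call.supporting_rule == "high_seg_count"

    def test_intermediate_with_large_segment_support(self):
        call = classify_ploidy(self._profile(30, 0.05, big_segment=True))
        assert call.label == "aneuploid"
        assert call.supporting_rule == "intermediate_with_support"

    def test_intermediate_without_support_diploid(self):
        # deviation 0.05 on a 2-bin (0.44 Mb) segment: below both support gates
        assert classify_ploidy(self._profile(30, 0.05, big_segment=False)).label == "diploid"

    def test_intermediate_low_deviation_diploid(self):
        assert classify_ploidy(self._profile(30, 0.01, big_segment=True)).label == "diploid"

    def test_boundary_segment_counts(self):
        # 46 segments / dev 0.031 passes the high-count branch; 45 falls to the
        # intermediate branch and then needs size or value support
        assert classify_ploidy(self._profile(46, 0.031)).supporting_rule == "high_seg_count"
        call45 = classify_ploidy(self._profile(45, 0.031))
        assert call45.label == "diploid"
        call45_big = classify_ploidy(self._profile(45, 0.031, big_segment=True))
        assert call45_big.label == "aneuploid"
        assert call45_big.supporting_rule == "intermediate_with_support"

    def test_high_value_support_without_size(self):
        call = classify_ploidy(self._profile(30, 0.12, big_segment=False))
        assert call.label == "aneuploid"


class TestAnnotateGenes:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_contained_gene_reported(self):
        calls = [CNACall("chr1", 1000, 5000, "amplification", 1.5, 2)]
        out = annotate_genes(calls, self._genes([("chr1", 2000, 3000, "G1")]))
        assert out[0][1] == ["G1"]

    def test_abutting_gene_not_reported(self):
        calls = [CNACall("chr1", 1000, 5000, "amplification", 1.5, 2)]
        out = annotate_genes(calls, self._genes([("chr1", 5000, 6000, "G1")]))
        assert out[0][1] == []

    def test_random_intervals_match_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        calls = []
        for _ in range(100):
            s = int(rng.integers(0, 10_000))
            calls.append(CNACall("chr1", s, s + int(rng.integers(1, 500)), "deletion", 0.5, 1))
        genes = self._genes(
            [
                ("chr1", int(s), int(s) + int(l), f"g{i}")
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 10_000, 100), rng.integers(1, 500, 100))
                )
            ]
        )
        out = annotate_genes(calls, genes)
        for call, hits in out:
            expected = sorted(
                g.name
                for g in genes.itertuples()
                if g.chrom == call.chrom and g.start < call.end_bp and call.start_bp < g.end
            )
            assert hits == expected


class TestCorrelation:
    def test_self_correlation_is_one(self, grid):
        vals = np.ones(100)
        vals[10:30] = 1.4
        p = make_profile(grid, vals)
        assert plasma_tissue_correlation(p, p) == pytest.approx(1.0)

    def test_exact_anticorrelation(self, grid):
        vals = np.ones(100)
        vals[10:30] = 1.4
        a = make_profile(grid, vals)
        b = make_profile(grid, 2.0 - vals)
        assert plasma_tissue_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, grid):
        rng = np.random.default_rng(4)
        va, vb = rng.normal(1, 0.2, 100), rng.normal(1, 0.2, 100)
        a, b = make_profile(grid, va), make_profile(grid, vb)
        x, y = a.per_bin_segvalue, b.per_bin_segvalue
        direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert plasma_tissue_correlation(a, b) == pytest.approx(direct)

    def test_grid_mismatch_rejected(self, grid):
        other = BinGrid.uniform({"chr2": 220_000 * 100}, 220_000)
        with pytest.raises(GridMismatch):
            plasma_tissue_correlation(make_profile(grid, np.ones(100)), make_profile(other, np.ones(100)))

    def test_zero_variance_is_nan(self, grid):
        a = make_profile(grid, np.ones(100))
        vals = np.ones(100)
        vals[0] = 1.5
        assert np.isnan(plasma_tissue_correlation(a, make_profile(grid, vals)))


class TestMutationConcordance:
    def test_identities(self):
        a = {("chr1", 1, "A", "G"), ("chr1", 2, "C", "T"), ("chr2", 3, "G", "A")}
        assert mutation_concordance(a, a) == 100.0
        assert mutation_concordance(a, {("chrX", 9, "T", "C")}) == 0.0

    def test_half_overlap(self):
        assert mutation_concordance({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(50.0)

    def test_empty_union_is_nan(self):
        assert np.isnan(mutation_concordance(set(), set()))

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
    )
    def test_symmetric_and_bounded(self, a, b):
        if not (a | b):
            return
        v = mutation_concordance(a, b)
        assert v == mutation_concordance(b, a)
        assert 0.0 <= v <= 100.0
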