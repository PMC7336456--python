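import numpy as np
import pandas as pd
import pytest

from cfevo.cnv import BinCounts, BinGrid, SegmentProfile


@pytest.fixture
def grid_1000():
    """1000 bins of 220 kb on one chromosome."""
    return BinGrid.uniform({"chr1": 220_000 * 1000}, 220_000)


@pytest.fixture
def grid_small():
    """10 bins of 100 bp on one chromosome."""
    return BinGrid.uniform({"chr1": 1000}, 100)


def make_profile(grid, per_bin_values, breaks_by_chrom=None):
    """SegmentProfile from per-bin values; segments split at value changes
    (or at the supplied per-chromosome break offsets)."""
    per_bin_values = np.asarray(per_bin_values, dtype=float)
    rows = []
    per_bin = np.empty(len(grid))
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        vals = per_bin_values[sl]
        if breaks_by_chrom is None:
            cps = (np.flatnonzero(np.diff(vals) != 0) + 1).tolist()
        else:
            cps = list(breaks_by_chrom.get(chrom, []))
        bounds = [0] + cps + [len(vals)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo, hi = sl.start + a, sl.start + b
            mean = float(per_bin_values[lo:hi].mean())
            per_bin[lo:hi] = mean
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": lo,
                    "end_bin": hi - 1,
                    "start_bp": int(grid.start[lo]),
                    "end_bp": int(grid.end[hi - 1]),
                    "n_bins": hi - lo,
                    "mean_ratio": mean,
                }
            )
    return SegmentProfile(grid=grid, segments=pd.DataFrame(rows), per_bin_segvalue=per_bin)


def engineered_variant_frame() -> pd.DataFrame:
    """20 records spanning every branch of the somatic filter cascade."""
    from cfevo.recovery import engineered_filter_table

    return engineered_filter_table()


def cascade_oracle(df: pd.DataFrame) -> set:
    """Brute-force re-evaluation of the filter rules straight off the table."""
    keep = set()
    for r in df.itertuples():
        status = set(str(r.filter).split(";"))
        if not status & {"PASS", "germline_risk"}:
            continue
        if r.depth_t1 <= 0 or r.alt_t1 / r.depth_t1 < 0.07:
            continue
        if r.normal_depth < 100:
            if r.normal_alt > 2:
                continue
        elif r.normal_alt / r.normal_depth > 0.01:
            continue
        keep.add((r.chrom, r.pos, r.ref, r.alt))
    return keep


@pytest.fixture
def engineered_df():
    return engineered_variant_frame()


@pytest.fixture
def engineered_vcf(tmp_path, engineered_df):
    from cfevo.io import write_vcf

    path = tmp_path / "engineered.vcf"
    write_vcf(engineered_df, path)
    return path
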