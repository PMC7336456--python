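"""CNA calling on segmented profiles, aneuploid/diploid classification,
gene annotation, and plasma-tissue concordance.

The copy-neutral state is the genome-wide median of per-bin segmentation
values. A CNA is a maximal run of consecutive bins within one chromosome
sharing a segmentation value that deviates from neutral; its length is the
end position of its last bin minus the start position of its first bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnv import SegmentProfile
from .errors import GridMismatch, InvalidArgument

logger = logging.getLogger(__name__)

__all__ = [
    "CNACall",
    "PloidyCall",
    "PloidyThresholds",
    "neutral_level",
    "call_cnas",
    "cna_burden",
    "classify_ploidy",
    "annotate_genes",
    "plasma_tissue_correlation",
    "mutation_concordance",
]


@dataclass(frozen=True)
class CNACall:
    """One amplified or deleted run of bins."""

    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # "amplification" | "deletion"
    seg_ratio: float
    n_bins: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class PloidyThresholds:
    """Thresholds of the aneuploid/diploid classification rule.

    A profile is aneuploid with > seg_high segments and a deviation from the
    median segmentation value > deviation_min; with an intermediate segment
    count (seg_low..seg_high) it additionally needs a deviating segment that
    is large (>= large_segment_bp) or strongly deviating (>= high_value_dev).
    """

    seg_high: int = 45
    seg_low: int = 25
    deviation_min: float = 0.03
    large_segment_bp: int = 10_000_000
    high_value_dev: float = 0.10

    def __post_init__(self):
        if self.seg_low >= self.seg_high:
            raise InvalidArgument("seg_low must be < seg_high")
        if self.deviation_min <= 0:
            raise InvalidArgument("deviation_min must be > 0")


@dataclass(frozen=True)
class PloidyCall:
    label: str  # "aneuploid" | "diploid"
    n_segments: int
    max_abs_deviation: float
    supporting_rule: str  # high_seg_count | intermediate_with_support | diploid_default


def neutral_level(profile: SegmentProfile) -> float:
    """Copy-neutral state: median segmentation value over all genomic bins.

    Even bin counts use the midpoint of the two central order statistics.
    """
    return float(np.median(profile.per_bin_segvalue))


def call_cnas(profile: SegmentProfile, neutral: float, tol: float = 1e-9) -> list[CNACall]:
    """Maximal runs of bins with the same segmentation value off neutral.

    Runs are bounded by chromosome; two non-adjacent altered runs yield two
    calls. ``tol`` is the deviation below which a value counts as neutral
    (default effectively exact inequality, appropriate after MergeLevels).
    """
    grid = profile.grid
    vals = profile.per_bin_segvalue
    calls: list[CNACall] = []
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        i = sl.start
        while i < sl.stop:
            v = vals[i]
            j = i
            while j + 1 < sl.stop and vals[j + 1] == v:
                j += 1
            if abs(v - neutral) > tol:
                calls.append(
                    CNACall(
                        chrom=chrom,
                        start_bp=int(grid.start[i]),
                        end_bp=int(grid.end[j]),
                        direction="amplification" if v > neutral else "deletion",
                        seg_ratio=float(v),
                        n_bins=j - i + 1,
                    )
                )
            i = j + 1
    return calls


def cna_burden(calls: list[CNACall], baseline: float, neutral: float = 1.0) -> int:
    """Number of CNAs whose segmentation ratio deviates >= baseline from neutral."""
    if baseline < 0:
        raise InvalidArgument("baseline must be >= 0")
    return sum(1 for c in calls if abs(c.seg_ratio - neutral) >= baseline)


def classify_ploidy(
    profile: SegmentProfile, thresholds: PloidyThresholds = PloidyThresholds()
) -> PloidyCall:
    """Aneuploid/diploid call from segment count and deviation from median.

    Aneuploid when the profile has many segments (> seg_high) and any segment
    deviates from the median segmentation value by more than deviation_min;
    an intermediate segment count (seg_low..seg_high inclusive) also needs a
    deviating segment that is physically large or strongly deviating. All
    other profiles are diploid.
    """
    segs = profile.segments
    med = float(np.median(profile.per_bin_segvalue))
    dev = (segs["mean_ratio"] - med).abs().to_numpy()
    max_dev = float(dev.max()) if len(dev) else 0.0
    n = len(segs)
    t = thresholds
    if n > t.seg_high and max_dev > t.deviation_min:
        return PloidyCall("aneuploid", n, max_dev, "high_seg_count")
    if t.seg_low <= n <= t.seg_high and max_dev > t.deviation_min:
        deviating = dev > t.deviation_min
        span = (segs["end_bp"] - segs["start_bp"]).to_numpy()
        if np.any(deviating & (span >= t.large_segment_bp)) or np.any(
            dev >= t.high_value_dev
        ):
            return PloidyCall("aneuploid", n, max_dev, "intermediate_with_support")
    return PloidyCall("diploid", n, max_dev, "diploid_default")


def annotate_genes(
    calls: list[CNACall], genes: pd.DataFrame
) -> list[tuple[CNACall, list[str]]]:
    """Genes overlapping each CNA by >= 1 bp under half-open semantics.

    ``genes`` needs columns chrom/start/end/name (BED convention). A gene
    whose start equals a CNA's end does not overlap.
    """
    for col in ("chrom", "start", "end", "name"):
        if col not in genes.columns:
            raise InvalidArgument(f"gene table lacks column {col!r}")
    trees: dict = {}
    for row in genes.itertuples():
        if row.end <= row.start:
            raise InvalidArgument(f"malformed gene interval at table row {row.Index}")
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    out = []
    for call in calls:
        tree = trees.get(call.chrom)
        hits = sorted(iv.data for iv in tree.overlap(call.start_bp, call.end_bp)) if tree else []
        out.append((call, hits))
    return out


def plasma_tissue_correlation(
    profile_a: SegmentProfile, profile_b: SegmentProfile
) -> float:
    """Pearson correlation of per-bin segmentation values on a shared grid.

    Returns NaN (with a log message) when either profile has zero variance.
    """
    if profile_a.grid != profile_b.grid:
        raise GridMismatch("profiles are on different bin grids")
    a = profile_a.per_bin_segvalue
    b = profile_b.per_bin_segvalue
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("correlation undefined: zero variance in a profile")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mutation_concordance(set_a, set_b) -> float:
    """Percent concordant mutations: 100 * |A n B| / |A u B| (NaN when both empty)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return float("nan")
    return 100.0 * len(a & b) / len(union)
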