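"""Sparse-WGS copy-number profiling: binned read counts, normalization,
circular binary segmentation (CBS), and MergeLevels post-processing.

The segmentation substrate is a genome-wide grid of bins (0-based half-open,
~220 kb mean size for 0.1X plasma WGS). Read counts per bin are normalized to
a genome-mean ratio of 1, segmented per chromosome by recursive CBS with
permutation significance, pruned (``undo.prune``-style), and finally adjacent
segments whose bin-ratio distributions are statistically indistinguishable are
merged (MergeLevels). A simplified tumor/normal exome depth-ratio profile is
also provided so exome targets can be segmented on target order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgument

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "BinCounts",
    "SegmentProfile",
    "CBSParams",
    "count_reads_in_bins",
    "normalize",
    "cbs_segment",
    "merge_levels",
    "exome_cn_ratio",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinGrid:
    """Ordered genomic bins, 0-based half-open, non-overlapping.

    Bins must be sorted by (chromosome, start) with chromosomes contiguous in
    the order of first appearance.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        if not (len(chrom) == len(start) == len(end)):
            raise InvalidArgument("grid columns must have equal length")
        if len(chrom) == 0:
            raise InvalidArgument("grid is empty")
        if np.any(end <= start):
            raise InvalidArgument("bins must satisfy start < end")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        # per-chromosome sortedness / non-overlap
        for c in self.chromosomes:
            idx = np.flatnonzero(chrom == c)
            if np.any(np.diff(idx) != 1):
                raise InvalidArgument(f"bins of {c} are not contiguous")
            s, e = start[idx], end[idx]
            if np.any(s[1:] < e[:-1]):
                raise InvalidArgument(f"bins of {c} overlap or are unsorted")

    def __len__(self) -> int:
        return len(self.start)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    @property
    def chromosomes(self) -> list:
        """Chromosome names in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @classmethod
    def uniform(cls, chrom_lengths: dict, bin_size: int = 220_000) -> "BinGrid":
        """Equal-width bins tiling each chromosome (last bin truncated)."""
        if bin_size <= 0:
            raise InvalidArgument("bin_size must be positive")
        chroms, starts, ends = [], [], []
        for c, length in chrom_lengths.items():
            edges = np.arange(0, length, bin_size, dtype=np.int64)
            chroms.extend([c] * len(edges))
            starts.extend(edges.tolist())
            ends.extend(np.minimum(edges + bin_size, length).tolist())
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BinGrid":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(np.int64),
            df["end"].to_numpy(np.int64),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})


@dataclass
class BinCounts:
    """Raw and normalized read counts keyed to a :class:`BinGrid`."""

    grid: BinGrid
    raw: np.ndarray
    ratio: np.ndarray | None = None
    log2ratio: np.ndarray | None = None
    zero_flag: np.ndarray | None = None  # bins whose log2 ratio was floored
    truth_ratio: np.ndarray | None = None  # simulator ground truth, if any
    n_dropped_reads: int = 0

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if len(self.raw) != len(self.grid):
            raise InvalidArgument("raw counts length does not match grid")
        if np.any(self.raw < 0):
            raise InvalidArgument("raw counts must be non-negative")


@dataclass
class SegmentProfile:
    """Piecewise-constant segmentation of a :class:`BinCounts` profile.

    ``segments`` has columns chrom, start_bin, end_bin (inclusive bin indices
    into the grid), start_bp, end_bp, n_bins, mean_ratio. ``per_bin_segvalue``
    is the segment mean broadcast to every member bin.
    """

    grid: BinGrid
    segments: pd.DataFrame
    per_bin_segvalue: np.ndarray

    def __post_init__(self):
        if len(self.per_bin_segvalue) != len(self.grid):
            raise InvalidArgument("per-bin segment values do not match grid")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class CBSParams:
    """Tuning knobs for circular binary segmentation.

    alpha is the permutation significance level for accepting a split;
    undo_prune removes changepoints whose removal raises the residual sum of
    squares by less than ``undo_prune`` times the current residual.
    """

    alpha: float = 0.0001
    undo_prune: float = 0.05
    n_permutations: int = 10_000
    min_seg_bins: int = 2
    seed: int = 0
    segment_log2: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidArgument("alpha must be in (0, 1)")
        if self.undo_prune < 0:
            raise InvalidArgument("undo_prune must be >= 0")
        if self.n_permutations < 1 or self.min_seg_bins < 1:
            raise InvalidArgument("n_permutations and min_seg_bins must be >= 1")


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------


def count_reads_in_bins(read_positions, grid: BinGrid) -> BinCounts:
    """Assign aligned-read start positions to grid bins.

    ``read_positions`` is an iterable of (chrom, pos) or a DataFrame with
    chrom/pos columns. Inclusion is 0-based half-open: a read at a bin start
    belongs to that bin; a read at a bin end belongs to the next bin. Reads on
    unknown chromosomes or outside every bin are dropped and counted.
    """
    if isinstance(read_positions, pd.DataFrame):
        df = read_positions[["chrom", "pos"]]
    else:
        df = pd.DataFrame(list(read_positions), columns=["chrom", "pos"])
    counts = np.zeros(len(grid), dtype=np.int64)
    dropped = 0
    known = set(grid.chromosomes)
    for c, sub in df.groupby("chrom", sort=False):
        if c not in known:
            dropped += len(sub)
            warnings.warn(f"dropping {len(sub)} reads on unknown chromosome {c!r}")
            continue
        sl = grid.chrom_slice(c)
        starts, ends = grid.start[sl], grid.end[sl]
        pos = sub["pos"].to_numpy(np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        dropped += int(np.sum(~inside))
        np.add.at(counts, sl.start + idx[inside], 1)
    return BinCounts(grid=grid, raw=counts, n_dropped_reads=dropped)


def normalize(counts: BinCounts) -> BinCounts:
    """Fill ratio and log2 ratio; ratios are counts divided by the genome mean.

    mean(ratio) is exactly 1. Zero-count bins keep ratio 0 but their log2
    ratio is floored at log2(1 / (2 * mean raw count)) and flagged, so sparse
    data never produce -inf.
    """
    raw = counts.raw.astype(float)
    total = raw.sum()
    if total <= 0:
        raise InvalidArgument("all bins have zero counts; cannot normalize")
    mean_raw = total / len(raw)
    ratio = raw / mean_raw
    floor = 1.0 / (2.0 * mean_raw)
    zero = ratio == 0
    log2ratio = np.log2(np.where(zero, floor, ratio))
    if zero.any():
        logger.info("floored %d zero-count bins at ratio %.3g", zero.sum(), floor)
    return replace(counts, ratio=ratio, log2ratio=log2ratio, zero_flag=zero)


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


def _max_arc_stat(x: np.ndarray, sigma: float, min_w: int):
    """Maximal two-sample arc statistic over arcs (i, j] of x.

    Returns (stat, i, j). Wrapped arcs are redundant because the statistic is
    symmetric in arc/complement, so only i < j is scanned. Arc lengths are
    restricted to [min_w, n - min_w] so both resulting parts are non-trivial.
    """
    n = len(x)
    if n < 2 * min_w or sigma <= 0:
        return 0.0, 0, n
    s = np.concatenate(([0.0], np.cumsum(x - x.mean())))
    best, bi, bj = 0.0, 0, n
    for m in range(min_w, n - min_w + 1):
        d = s[m:] - s[: n - m + 1]
        k = int(np.argmax(np.abs(d)))
        val = abs(d[k]) / np.sqrt(m * (n - m) / n)
        if val > best:
            best, bi, bj = val, k, k + m
    return best / sigma, bi, bj


def _arc_exceeds(
    s: np.ndarray, sigma: float, min_w: int, obs: float, r_span: float, m_abs: float
) -> bool:
    """Does the max arc statistic of a permutation reach ``obs``?

    ``s`` is the centered cumulative sum (length n). Only arc lengths whose
    numerator bound min(R, m*M, (n-m)*M) can still reach ``obs`` are scanned,
    most promising first, with early exit on the first exceedance.
    """
    n = len(s)
    m = np.arange(min_w, n - min_w + 1)
    den = np.sqrt(m * (n - m) / n)
    num_bound = np.minimum(np.minimum(m * m_abs, (n - m) * m_abs), r_span)
    b = num_bound / (sigma * den)
    cand = np.flatnonzero(b >= obs)
    if cand.size == 0:
        return False
    s0 = np.concatenate(([0.0], s))
    for k in cand[np.argsort(-b[cand])]:
        mm = int(m[k])
        d = s0[mm:] - s0[: n - mm + 1]
        if np.max(np.abs(d)) / (sigma * den[k]) >= obs:
            return True
    return False


def _perm_significant(x: np.ndarray, obs: float, params: CBSParams, rng) -> bool:
    """Permutation test: is the observed max-arc statistic significant?

    The split is accepted iff exceedances / n_permutations < alpha. A cheap
    O(n) bound screens each permutation before the exact O(n^2) scan: an arc
    of length m has numerator at most min(R, m * M), where R is the centered
    partial-sum range and M the largest centered value — both cheap per
    permutation — and the resulting bound over m peaks at m0 = R / M. Early
    stop as soon as the exceedance count rules out significance.
    """
    n = len(x)
    sigma = float(np.std(x))
    if sigma == 0:
        return False
    min_w = params.min_seg_bins
    m_abs = float(np.max(np.abs(x - x.mean())))  # permutation-invariant
    k_stop = params.alpha * params.n_permutations
    exceed = 0
    done = 0
    chunk = max(1, min(512, params.n_permutations))
    while done < params.n_permutations:
        c = min(chunk, params.n_permutations - done)
        perms = rng.permuted(np.broadcast_to(x, (c, n)).copy(), axis=1)
        s = np.cumsum(perms - perms.mean(axis=1, keepdims=True), axis=1)
        span = np.maximum(s.max(axis=1), 0.0) - np.minimum(s.min(axis=1), 0.0)
        m0 = np.clip(span / max(m_abs, 1e-300), min_w, n / 2)
        bound = span / (sigma * np.sqrt(m0 * (n - m0) / n))
        for row in np.flatnonzero(bound >= obs):
            if _arc_exceeds(s[row], sigma, min_w, obs, float(span[row]), m_abs):
                exceed += 1
        done += c
        if exceed >= k_stop:
            return False
    return exceed / params.n_permutations < params.alpha


def _find_changepoints(x: np.ndarray, params: CBSParams, rng) -> list[int]:
    """Recursive CBS on one chromosome; returns sorted internal breakpoints."""
    out: list[int] = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_seg_bins:
            return
        sigma = float(np.std(seg))
        if sigma == 0:
            return
        obs, i, j = _max_arc_stat(seg, sigma, params.min_seg_bins)
        if obs <= 0:
            return
        if not _perm_significant(seg, obs, params, rng):
            return
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        if not cuts:
            return
        for c in cuts:
            out.append(lo + c)
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(x))
    return sorted(out)


def _ssr(x: np.ndarray, cps: list[int]) -> float:
    bounds = [0] + list(cps) + [len(x)]
    tot = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        tot += float(np.sum((seg - seg.mean()) ** 2))
    return tot


def _undo_prune(x: np.ndarray, cps: list[int], undo_prune: float) -> list[int]:
    """Remove changepoints whose removal barely increases the residual SSR."""
    cps = sorted(cps)
    while cps:
        current = _ssr(x, cps)
        deltas = [(_ssr(x, cps[:k] + cps[k + 1 :]) - current, k) for k in range(len(cps))]
        delta, k = min(deltas)
        if delta < undo_prune * current:
            cps.pop(k)
        else:
            break
    return cps


def _profile_from_changepoints(
    counts: BinCounts, cps_by_chrom: dict, values: np.ndarray
) -> SegmentProfile:
    grid = counts.grid
    per_bin = np.empty(len(grid), dtype=float)
    rows = []
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        cps = cps_by_chrom.get(chrom, [])
        bounds = [0] + list(cps) + [sl.stop - sl.start]
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo, hi = sl.start + a, sl.start + b
            mean = float(values[lo:hi].mean())
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


def cbs_segment(counts: BinCounts, params: CBSParams = CBSParams()) -> SegmentProfile:
    """Circular binary segmentation of normalized bin ratios, per chromosome.

    Recursively finds the arc maximizing the two-sample statistic between
    in-arc and out-of-arc bins, accepts a split when its permutation p-value
    is below alpha, then prunes changepoints whose removal changes the
    residual sum of squares by less than ``undo_prune`` of the total.
    Chromosomes with fewer than ``min_seg_bins`` bins come back as one segment.
    """
    if counts.ratio is None:
        counts = normalize(counts)
    values = counts.log2ratio if params.segment_log2 else counts.ratio
    rng = np.random.default_rng(params.seed)
    grid = counts.grid
    cps_by_chrom = {}
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        x = np.asarray(values[sl], dtype=float)
        cps = _find_changepoints(x, params, rng)
        if cps and params.undo_prune > 0:
            cps = _undo_prune(x, cps, params.undo_prune)
        cps_by_chrom[chrom] = cps
    return _profile_from_changepoints(counts, cps_by_chrom, np.asarray(values, float))


# ---------------------------------------------------------------------------
# MergeLevels
# ---------------------------------------------------------------------------


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def merge_levels(
    profile: SegmentProfile, counts: BinCounts, merge_p_threshold: float = 0.05
) -> SegmentProfile:
    """Join adjacent segments with non-significant rank-sum differences.

    Repeatedly merges the within-chromosome adjacent pair whose member-bin
    ratios have the largest Mann-Whitney p-value, while that p-value is at or
    above the threshold; segment means are recomputed after each merge. The
    result is a fixed point: re-running changes nothing.
    """
    if counts.ratio is None:
        raise InvalidArgument("counts must be normalized before merge_levels")
    values = np.asarray(counts.ratio, dtype=float)
    segs = [
        (row.chrom, int(row.start_bin), int(row.end_bin))
        for row in profile.segments.itertuples()
    ]
    changed = True
    while changed:
        changed = False
        best_p, best_k = -1.0, -1
        for k in range(len(segs) - 1):
            c1, s1, e1 = segs[k]
            c2, s2, e2 = segs[k + 1]
            if c1 != c2:
                continue
            p = _ranksum_p(values[s1 : e1 + 1], values[s2 : e2 + 1])
            if p > best_p:
                best_p, best_k = p, k
        if best_k >= 0 and best_p >= merge_p_threshold:
            c, s1, _ = segs[best_k]
            _, _, e2 = segs.pop(best_k + 1)
            segs[best_k] = (c, s1, e2)
            changed = True
    cps_by_chrom: dict = {}
    grid = profile.grid
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        cps_by_chrom[chrom] = sorted(
            s - sl.start for c, s, _ in segs if c == chrom and s > sl.start
        )
    return _profile_from_changepoints(counts, cps_by_chrom, values)


# ---------------------------------------------------------------------------
# exome depth ratio
# ---------------------------------------------------------------------------


def exome_cn_ratio(
    tumor_depth: np.ndarray, normal_depth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Median-centered log2 tumor/normal depth ratio per exome target.

    ratio_t = (tumor_t / sum tumor) / (normal_t / sum normal). Targets with
    zero normal depth are excluded; returns (log2 ratios with NaN at excluded
    targets, boolean mask of excluded targets).
    """
    t = np.asarray(tumor_depth, dtype=float)
    n = np.asarray(normal_depth, dtype=float)
    if t.shape != n.shape:
        raise InvalidArgument("depth vectors must have equal length")
    excluded = n <= 0
    if excluded.all():
        raise InvalidArgument("no targets with positive normal depth")
    if excluded.any():
        logger.warning("excluding %d targets with zero normal depth", excluded.sum())
    keep = ~excluded
    # half-read floor on tumor depth avoids -inf log ratios at empty targets
    tk = np.maximum(t[keep], 0.5)
    ratio = (tk / tk.sum()) / (n[keep] / n[keep].sum())
    log2 = np.log2(ratio)
    log2 = log2 - np.median(log2)
    out = np.full(t.shape, np.nan)
    out[keep] = log2
    return out, excluded
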