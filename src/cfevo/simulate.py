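"""Synthetic patient and cohort generation for the plasma-sequencing pipeline.

Every downstream stage (fragment QC, bin-count segmentation, variant
filtering, clonal inference, survival statistics) is exercised against data
generated here with known ground truth: rooted clone trees with CNA/SNV
payloads under a perfect phylogeny, purity-diluted overdispersed bin counts,
binomially sampled per-timepoint variant read counts, bimodal fragment-size
mixtures with di-/tri-nucleosome harmonics, and ploidy-linked survival times.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import BinCounts, BinGrid
from .errors import InvalidArgument
from .fragment_qc import DEFAULT_MASS_SCALE, MASS_PER_BP_NG

__all__ = [
    "DEFAULT_GENOME",
    "CloneTruth",
    "CloneTree",
    "simulate_clone_tree",
    "simulate_bin_counts",
    "simulate_variants",
    "simulate_fragment_sizes",
    "simulate_cohort_clinical",
    "simulate_segment_means",
]

# small synthetic genome: 4 chromosomes of 55 Mb -> 1000 bins at 220 kb
DEFAULT_GENOME = {f"chr{i}": 55_000_000 for i in range(1, 5)}


@dataclass
class CloneTruth:
    """One clone: private payloads plus its lineage prevalence per timepoint.

    ``prevalence`` is the fraction of tumor cells carrying this clone's
    mutations (itself plus all descendants); a parent's prevalence covers the
    sum of its children's at every timepoint. Payload entries are private to
    the clone — descendants inherit them (perfect phylogeny).
    """

    clone_id: int
    parent_id: int | None  # None for the root clone
    cna_payload: list = field(default_factory=list)  # (chrom, start, end, copy_number)
    snv_payload: list = field(default_factory=list)  # (chrom, pos, multiplicity)
    prevalence: np.ndarray = field(default_factory=lambda: np.array([1.0]))


@dataclass
class CloneTree:
    """A rooted clone tree with per-timepoint frequencies."""

    clones: list[CloneTruth]

    def __post_init__(self):
        self.validate()

    @property
    def n_timepoints(self) -> int:
        return len(self.clones[0].prevalence)

    def children(self, clone_id: int) -> list[CloneTruth]:
        return [c for c in self.clones if c.parent_id == clone_id]

    def ancestors(self, clone_id: int) -> list[int]:
        by_id = {c.clone_id: c for c in self.clones}
        out = []
        p = by_id[clone_id].parent_id
        while p is not None:
            out.append(p)
            p = by_id[p].parent_id
        return out

    def full_cna_payload(self, clone_id: int) -> list:
        by_id = {c.clone_id: c for c in self.clones}
        ids = [clone_id] + self.ancestors(clone_id)
        return [e for i in ids for e in by_id[i].cna_payload]

    def clone_frequency_matrix(self) -> np.ndarray:
        """Disjoint clone frequencies (K x T): prevalence minus children's sum."""
        prev = np.stack([c.prevalence for c in self.clones])
        freq = prev.copy()
        for i, c in enumerate(self.clones):
            ch = [j for j, d in enumerate(self.clones) if d.parent_id == c.clone_id]
            if ch:
                freq[i] = prev[i] - prev[ch].sum(axis=0)
        return np.clip(freq, 0.0, None)

    def validate(self, eps: float = 1e-9):
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise InvalidArgument("clone tree must have exactly one root")
        if np.any(roots[0].prevalence > 1 + eps):
            raise InvalidArgument("root prevalence exceeds 1")
        for c in self.clones:
            ch = self.children(c.clone_id)
            if ch:
                kids = np.sum([k.prevalence for k in ch], axis=0)
                if np.any(c.prevalence < kids - eps):
                    raise InvalidArgument("prevalence sum constraint violated")


def _sample_disjoint_regions(rng, genome: dict, n: int, min_mb=2, max_mb=15):
    """Non-overlapping genomic intervals, Mb-granular."""
    taken: dict = {c: [] for c in genome}
    out = []
    attempts = 0
    while len(out) < n and attempts < 1000:
        attempts += 1
        chrom = list(genome)[rng.integers(len(genome))]
        length = int(rng.integers(min_mb, max_mb + 1)) * 1_000_000
        start = int(rng.integers(0, max(1, (genome[chrom] - length) // 1_000_000))) * 1_000_000
        end = start + length
        if any(s < end and start < e for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, end))
        out.append((chrom, start, end))
    return out


def simulate_clone_tree(
    n_clones: int,
    n_timepoints: int,
    expansion_scenario: str = "stable_dominant",
    seed: int = 0,
    genome: dict | None = None,
    n_cna_per_clone: int = 3,
    n_snv_per_clone: int = 20,
    min_prevalence_separation: float = 0.15,
) -> CloneTree:
    """Rooted clone tree with payloads and per-timepoint frequencies.

    ``expanding_minor`` plants a leaf clone starting minor (prevalence in the
    1-21% range observed for resistance-associated subclones) that expands to
    a strictly larger final frequency; ``stable_dominant`` keeps the largest
    clone's frequency within 0.05 across timepoints. Clone prevalence
    trajectories are rejection-sampled to stay at least
    ``min_prevalence_separation`` apart on average, emulating subclones that
    are actually distinguishable by their cellular prevalence (clones closer
    than the assay's resolution would never be reported as separate). CNA
    payloads are drawn on disjoint genomic regions so inherited copy numbers
    never conflict; SNV payloads avoid CNA regions (copy-neutral sites,
    multiplicity 1).
    """
    if n_clones < 1 or n_clones > 8:
        raise InvalidArgument("n_clones must be in 1..8")
    if n_timepoints < 2 or n_timepoints > 6:
        raise InvalidArgument("n_timepoints must be in 2..6")
    if expansion_scenario not in ("expanding_minor", "stable_dominant"):
        raise InvalidArgument(f"unknown scenario {expansion_scenario!r}")
    if expansion_scenario == "expanding_minor" and n_clones < 2:
        raise InvalidArgument("expanding_minor needs at least 2 clones")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    k, t = n_clones, n_timepoints

    parents = [None] + [int(rng.integers(0, i)) for i in range(1, k)]

    def draw_frequencies():
        """Disjoint clone frequencies (K x T), summing to 1 per timepoint."""
        freq = np.zeros((k, t))
        if k == 1:
            freq[0] = 1.0
        elif expansion_scenario == "stable_dominant":
            d0 = rng.uniform(0.55, 0.8)
            rest_base = rng.dirichlet(np.ones(k - 1))
            for tt in range(t):
                d = d0 + rng.uniform(-0.02, 0.02)
                # rest shares jitter around a fixed base: every clone stays stable
                rest = rng.dirichlet(rest_base * 60 + 0.5) * (1 - d)
                freq[0, tt] = d
                freq[1:, tt] = rest
        else:  # expanding_minor: the last clone is a leaf (parents point backwards)
            e = k - 1
            start = rng.uniform(0.02, 0.20)
            final = rng.uniform(0.45, 0.75)
            traj = np.linspace(start, final, t) + rng.uniform(-0.01, 0.01, size=t)
            traj = np.clip(traj, 0.01, 0.9)
            traj[0] = min(start, 0.21)
            traj[-1] = max(final, traj[0] + 0.25)
            base = rng.dirichlet(np.ones(k - 1) * 2)
            for tt in range(t):
                freq[e, tt] = traj[tt]
                freq[:e, tt] = rng.dirichlet(base * 60 + 0.5) * (1 - traj[tt])
        return freq

    for _ in range(500):
        freq = draw_frequencies()
        # lineage prevalence: subtree sums
        prev = freq.copy()
        for i in range(k - 1, 0, -1):
            prev[parents[i]] += prev[i]
        sep = min(
            (
                float(np.mean(np.abs(prev[i] - prev[j])))
                for i in range(k)
                for j in range(i + 1, k)
            ),
            default=np.inf,
        )
        if sep >= min_prevalence_separation:
            break
    else:
        raise InvalidArgument(
            "could not draw clone trajectories with the requested separation"
        )

    regions = _sample_disjoint_regions(rng, genome, n_cna_per_clone * k)
    cn_choices = np.array([0, 1, 3, 4, 5])
    cn_probs = np.array([0.05, 0.35, 0.3, 0.2, 0.1])
    clones = []
    for i in range(k):
        cnas = [
            (c, s, e2, int(rng.choice(cn_choices, p=cn_probs)))
            for c, s, e2 in regions[i * n_cna_per_clone : (i + 1) * n_cna_per_clone]
        ]
        snvs = []
        while len(snvs) < n_snv_per_clone:
            chrom = list(genome)[rng.integers(len(genome))]
            pos = int(rng.integers(1, genome[chrom]))
            if any(c == chrom and s <= pos < e2 for c, s, e2 in [r[:3] for r in regions]):
                continue
            snvs.append((chrom, pos, 1))
        clones.append(
            CloneTruth(
                clone_id=i,
                parent_id=parents[i],
                cna_payload=cnas,
                snv_payload=snvs,
                prevalence=prev[i].copy(),
            )
        )
    return CloneTree(clones=clones)


def simulate_bin_counts(
    tree: CloneTree,
    purity: float,
    grid: BinGrid,
    mean_depth_per_bin: float = 50.0,
    overdispersion: float = 0.05,
    timepoint: int = 0,
    seed: int = 0,
) -> BinCounts:
    """Purity-diluted overdispersed bin counts for one timepoint.

    Expected counts are proportional to the purity-weighted mixture copy
    number over 2 (normal cells contribute copy number 2); counts are drawn
    gamma-mixed Poisson with a single dispersion parameter. The ground-truth
    expected ratio is attached as ``truth_ratio``.
    """
    if not 0 <= purity <= 1:
        raise InvalidArgument("purity must be in [0, 1]")
    if mean_depth_per_bin <= 0:
        raise InvalidArgument("mean depth per bin must be positive")
    if overdispersion < 0:
        raise InvalidArgument("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    freq = tree.clone_frequency_matrix()[:, timepoint]
    mids = (grid.start + grid.end) / 2
    tumor_cn = np.full(len(grid), 2.0)
    per_clone_cn = np.zeros((len(tree.clones), len(grid)))
    for i, clone in enumerate(tree.clones):
        cn = np.full(len(grid), 2.0)
        for chrom, s, e, c in tree.full_cna_payload(clone.clone_id):
            mask = (grid.chrom == chrom) & (mids >= s) & (mids < e)
            cn[mask] = c
        per_clone_cn[i] = cn
    residual = 1.0 - freq.sum()
    tumor_cn = per_clone_cn.T @ freq + max(residual, 0.0) * 2.0
    ratio = (purity * tumor_cn + (1 - purity) * 2.0) / 2.0
    mu = mean_depth_per_bin * ratio
    if overdispersion > 0:
        lam = rng.gamma(shape=1.0 / overdispersion, scale=overdispersion * mu)
    else:
        lam = mu
    raw = rng.poisson(lam)
    return BinCounts(grid=grid, raw=raw, truth_ratio=ratio)


_BASES = np.array(list("ACGT"))


def simulate_variants(
    tree: CloneTree,
    purity_by_timepoint,
    depth_plasma: int = 150,
    depth_normal: int = 80,
    contamination: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-timepoint variant read counts for every SNV in the tree.

    A mutation private to clone c is carried by c's whole lineage, so its
    expected VAF at timepoint t is
    purity_t * prevalence_c,t * multiplicity / (purity_t * CN + (1 - purity_t) * 2);
    alt counts are binomial at the stated depths. Matched-normal alt counts
    are binomial at ``contamination`` times the plasma VAF (default 0).
    """
    if depth_plasma <= 0 or depth_normal <= 0:
        raise InvalidArgument("depths must be positive")
    t = tree.n_timepoints
    purity = np.broadcast_to(np.asarray(purity_by_timepoint, dtype=float), (t,))
    if np.any((purity < 0) | (purity > 1)):
        raise InvalidArgument("purity values must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for clone in tree.clones:
        for chrom, pos, mult in clone.snv_payload:
            cn = 2
            for c2, s, e, cc in tree.full_cna_payload(clone.clone_id):
                if c2 == chrom and s <= pos < e:
                    cn = cc
            if cn < 1:
                continue
            vaf = purity * clone.prevalence * mult / (purity * cn + (1 - purity) * 2)
            alt = rng.binomial(depth_plasma, np.clip(vaf, 0, 1))
            nalt = rng.binomial(depth_normal, np.clip(contamination * vaf, 0, 1))
            ref_base = str(rng.choice(_BASES))
            alt_base = str(rng.choice(_BASES[_BASES != ref_base]))
            row = {
                "chrom": chrom,
                "pos": pos,
                "ref": ref_base,
                "alt": alt_base,
                "clone_id": clone.clone_id,
                "multiplicity": mult,
                "cn": cn,
                "normal_depth": depth_normal,
                "normal_alt": int(nalt[0]),
            }
            for tt in range(t):
                row[f"alt_t{tt + 1}"] = int(alt[tt])
                row[f"depth_t{tt + 1}"] = depth_plasma
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_fragment_sizes(
    tumor_fraction: float,
    n_fragments: int,
    seed: int = 0,
    tumor_mean_bp: float = 142.0,
    normal_mean_bp: float = 154.0,
    sd_bp: float = 20.0,
    harmonic_weights: tuple = (0.15, 0.05),
    mass_scale: float = DEFAULT_MASS_SCALE,
) -> tuple[np.ndarray, float]:
    """cfDNA fragment sizes: tumor/normal mixture with nucleosome harmonics.

    Each origin (tumor ~142 bp, normal ~154 bp) is a mixture of a
    mono-nucleosome component and di-/tri-nucleosome harmonics at 2x and 3x
    the mono-nucleosome location. The stated mean is the overall mixture mean
    (what a QC instrument reports for the sample), so the mono-nucleosome
    location is solved from the harmonic weights. Components are shifted
    gammas, keeping sizes positive. Returns (sizes, total mass in ng), the
    mass being n_fragments x mean size x mass-per-bp scaled to the plasma
    volume the sample represents.
    """
    if not 0 <= tumor_fraction <= 1:
        raise InvalidArgument("tumor_fraction must be in [0, 1]")
    if n_fragments <= 0:
        raise InvalidArgument("n_fragments must be positive")
    w2, w3 = harmonic_weights
    w1 = 1.0 - w2 - w3
    if w1 <= 0 or w2 < 0 or w3 < 0:
        raise InvalidArgument("harmonic weights must be non-negative and sum below 1")
    rng = np.random.default_rng(seed)
    is_tumor = rng.random(n_fragments) < tumor_fraction
    target_mean = np.where(is_tumor, tumor_mean_bp, normal_mean_bp)
    mono = target_mean / (w1 + 2 * w2 + 3 * w3)
    k = rng.choice([1, 2, 3], size=n_fragments, p=[w1, w2, w3])
    mean_k = mono * k
    sd_k = sd_bp * np.sqrt(k)
    # shifted gamma with shape 9: mean = loc + 3*sd, sd = sd_k, mode > 0
    loc = mean_k - 3 * sd_k
    sizes = loc + rng.gamma(shape=9.0, scale=sd_k / 3.0)
    sizes = np.maximum(sizes, 1.0)
    total_mass = float(sizes.sum() * MASS_PER_BP_NG * mass_scale)
    return sizes, total_mass


def simulate_cohort_clinical(
    n_patients: int,
    ploidy_effect: float = 1.67,
    seed: int = 0,
    aneuploid_fraction: float = 0.5,
    baseline_median_months: float = 21.0,
    censor_months: float = 60.0,
) -> pd.DataFrame:
    """Clinical table with ploidy-linked survival and cfDNA mass.

    Survival is exponential with hazard ln2 / baseline_median, multiplied by
    ``ploidy_effect`` for aneuploid patients; follow-up is administratively
    censored. Aneuploid patients draw higher total cfDNA (log-normal), and
    PSA is weakly correlated with cfDNA mass.
    """
    if n_patients < 2:
        raise InvalidArgument("need at least 2 patients")
    if ploidy_effect <= 0 or baseline_median_months <= 0:
        raise InvalidArgument("ploidy_effect and baseline median must be positive")
    rng = np.random.default_rng(seed)
    aneuploid = rng.random(n_patients) < aneuploid_fraction
    hazard = np.log(2) / baseline_median_months * np.where(aneuploid, ploidy_effect, 1.0)
    t_true = rng.exponential(1.0 / hazard)
    event = (t_true <= censor_months).astype(int)
    time = np.minimum(t_true, censor_months)
    z_cf = rng.normal(size=n_patients)
    cfdna = np.exp(np.log(3.0) + 0.9 * aneuploid + 1.0 * z_cf)
    z_psa = 0.12 * z_cf + np.sqrt(1 - 0.12**2) * rng.normal(size=n_patients)
    psa = np.exp(np.log(10.0) + 1.2 * z_psa)
    return pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:03d}" for i in range(n_patients)],
            "ploidy": np.where(aneuploid, "aneuploid", "diploid"),
            "survival_months": time,
            "event": event,
            "cfdna_ng": cfdna,
            "psa_ng_ml": psa,
        }
    )


def simulate_segment_means(
    aneuploid: bool,
    seed: int = 0,
    genome: dict | None = None,
    bin_size: int = 220_000,
    noise_sd: float = 0.01,
):
    """Noisy segment-level profile with a planted ploidy label.

    Returns a :class:`~cfevo.cnv.SegmentProfile`. Aneuploid profiles carry
    many segments (most beyond the classifier's high-count threshold) with
    real deviations from the neutral level; diploid profiles have few
    segments whose means wander only by measurement noise. Used by the
    ploidy-classifier recovery suite, which tests the classifier on its own
    substrate without re-running segmentation for every sample.
    """
    from .cnv import SegmentProfile, _profile_from_changepoints

    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    grid = BinGrid.uniform(genome, bin_size)
    values = np.ones(len(grid))
    cps_by_chrom = {}
    n_chrom = len(genome)
    if aneuploid:
        n_segments = int(rng.integers(48, 120))
    else:
        n_segments = int(rng.integers(1, 18))
    # distribute segment counts over chromosomes
    per_chrom = np.maximum(rng.multinomial(max(n_segments - n_chrom, 0), np.ones(n_chrom) / n_chrom) + 1, 1)
    for chrom, n_seg in zip(grid.chromosomes, per_chrom):
        sl = grid.chrom_slice(chrom)
        n_bins = sl.stop - sl.start
        if n_seg > 1:
            cps = np.sort(rng.choice(np.arange(2, n_bins - 1), size=min(n_seg - 1, n_bins // 3), replace=False))
        else:
            cps = np.array([], dtype=int)
        cps_by_chrom[chrom] = cps.tolist()
        bounds = [0] + cps.tolist() + [n_bins]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if aneuploid and rng.random() < 0.6:
                dev = rng.uniform(0.05, 0.5) * rng.choice([-1, 1])
            else:
                dev = 0.0
            values[sl.start + a : sl.start + b] = 1.0 + dev + rng.normal(0, noise_sd)
    counts = BinCounts(grid=grid, raw=np.ones(len(grid), dtype=np.int64))
    return _profile_from_changepoints(counts, cps_by_chrom, values)
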