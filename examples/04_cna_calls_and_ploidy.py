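"""CNA calling, ploidy classification, and plasma-tissue concordance.

The copy-neutral level is the median segmentation value; runs of bins off
that level become CNA calls with bp lengths. A profile with many deviating
segments is classified aneuploid. Two profiles on the same grid are compared
by Pearson correlation of their segmentation values, and mutation sets by
their concordance percentage."""

from cfevo.cna import (
    call_cnas,
    classify_ploidy,
    cna_burden,
    mutation_concordance,
    neutral_level,
    plasma_tissue_correlation,
)
from cfevo.cnv import BinGrid, cbs_segment, merge_levels, normalize, CBSParams
from cfevo.simulate import DEFAULT_GENOME, simulate_bin_counts, simulate_clone_tree

tree = simulate_clone_tree(2, 2, "stable_dominant", seed=3, n_cna_per_clone=6)
grid = BinGrid.uniform(DEFAULT_GENOME)

profiles = {}
for label, purity, seed in (("plasma", 0.5, 21), ("tissue", 0.9, 22)):
    counts = normalize(simulate_bin_counts(tree, purity, grid, seed=seed))
    profiles[label] = merge_levels(cbs_segment(counts, CBSParams(seed=seed)), counts)

plasma = profiles["plasma"]
neutral = neutral_level(plasma)
calls = call_cnas(plasma, neutral)
ploidy = classify_ploidy(plasma)
print(f"plasma: neutral level {neutral:.3f}, {len(calls)} CNAs "
      f"(burden at 0.03 baseline: {cna_burden(calls, 0.03, neutral)})")
for c in calls[:5]:
    print(f"  {c.chrom}:{c.start_bp // 1_000_000}-{c.end_bp // 1_000_000} Mb "
          f"{c.direction} ratio {c.seg_ratio:.2f} length {c.length_bp / 1e6:.1f} Mb")
print(f"ploidy call: {ploidy.label} ({ploidy.n_segments} segments, "
      f"rule {ploidy.supporting_rule})")

r = plasma_tissue_correlation(plasma, profiles["tissue"])
print(f"\nplasma vs tissue segmentation correlation r = {r:.2f}")
conc = mutation_concordance({"m1", "m2", "m3"}, {"m2", "m3", "m4"})
print(f"mutation concordance of two example call sets: {conc:.1f}%")
print("(high correlation means the plasma profile mirrors the tumor tissue)")
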