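"""Simulate one longitudinal patient: clone tree, sparse-WGS bin counts,
and per-timepoint variant read counts.

The clone tree carries CNA and SNV payloads under a perfect phylogeny; bin
counts are purity-diluted overdispersed counts on a 220 kb grid; variant alt
counts are binomial draws at the expected VAF given purity, prevalence and
local copy number."""

import numpy as np

from cfevo.cnv import BinGrid
from cfevo.simulate import (
    DEFAULT_GENOME,
    simulate_bin_counts,
    simulate_clone_tree,
    simulate_variants,
)

tree = simulate_clone_tree(3, 3, "expanding_minor", seed=11)
print("clone  parent  prevalence per timepoint")
for c in tree.clones:
    prev = "  ".join(f"{p:.2f}" for p in c.prevalence)
    print(f"  {c.clone_id}      {c.parent_id}     {prev}")
print("(a parent's prevalence always covers the sum of its children's)")

grid = BinGrid.uniform(DEFAULT_GENOME)  # 1000 bins of 220 kb
counts = simulate_bin_counts(tree, purity=0.6, grid=grid, seed=12)
altered = np.sum(counts.truth_ratio != 1.0)
print(f"\nbin counts: {len(grid)} bins, mean depth {counts.raw.mean():.1f}, "
      f"{altered} bins with a true copy-number signal")

table = simulate_variants(tree, [0.6, 0.6, 0.6], depth_plasma=300, seed=13)
vaf1 = (table["alt_t1"] / table["depth_t1"]).mean()
vaf3 = (table["alt_t3"] / table["depth_t3"]).mean()
print(f"variants: {len(table)} somatic SNVs, mean VAF {vaf1:.3f} at t1 -> "
      f"{vaf3:.3f} at t3")
print("(the expanding subclone's mutations gain allele frequency over time)")
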