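# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the simulator does and does not emulate, and the
design choices made where the design was genuinely open.

## Fragment QC

Concentration and size statistics are computed over fragments inside an
inclusive 100–700 bp gate (defaults in `QCConfig`), excluding high molecular
weight genomic DNA that contaminates archival plasma. The pass threshold is
2 ng of gated mass, inclusive, the minimum input for low-input library
construction. Mass per fragment defaults to length × 1.096e-12 ng/bp times a
configurable scale factor (default 1e6) mapping the sampled fragment list to
the plasma volume it represents; only relative masses matter for the
threshold, so the scale is a bookkeeping constant, not a physical claim.

Peak detection histograms sizes at 5 bp, smooths with a 7-bin moving
average (edge-padded), and calls maxima whose prominence reaches 5% of the
tallest smoothed bin. The smoothing width was chosen so multinomial counting
noise on a featureless histogram does not register as peaks at that
prominence; the instrument literature gives no peak-calling recipe, so both
knobs are explicit parameters. Peak structure is read from the whole
size-selected (< 1000 bp) trace rather than the 100–700 bp gate, because a
mono-nucleosome mode sitting near the gate boundary would otherwise lose its
left flank and become undetectable; mass, mean and mode stay gated.
Di-/tri-nucleosome harmonics are reported when secondary peaks lie within
±15 bp of 2× and 3× the primary mode.

## Copy-number segmentation

Input is a grid of 0-based half-open bins (default 220 kb) with raw counts.
Normalization divides by the genome-wide mean count, so mean(ratio) = 1
exactly; zero-count bins keep ratio 0 but their log2 ratio is floored at
log2(1/(2·mean raw)) and flagged, avoiding −∞ in sparse data. GC or
mappability corrections are not applied; counts are expected to come from a
variable-bin pipeline that already absorbed mappability.

CBS recursively scans each chromosome for the arc (i, j] maximizing
|S_j − S_i| / (σ̂·√(m(n−m)/n)) over arc lengths m in
[min_seg_bins, n − min_seg_bins] (wrapped arcs are redundant by the
statistic's arc/complement symmetry). The split is accepted when
(exceedances / n_permutations) < α with α = 1e-4 and 10,000 within-segment
label permutations, seeded; permutation testing stops early once the
exceedance count rules significance out. A per-permutation screening bound —
an arc of length m has numerator at most min(R, m·M, (n−m)·M) for
partial-sum range R and max centered value M, maximized near m₀ = R/M —
makes the exact O(n²) rescan rare, which is what keeps 10,000 permutations
per split affordable.

Undo-pruning then removes, iteratively, the changepoint whose removal
increases the residual sum of squares least, while that increase is below
`undo_prune` (default 0.05) times the current residual. This is an explicit
reading of "prune by SSR change"; equivalence with the reference R
implementation is asserted at the level of planted-changepoint recovery, not
bit-for-bit. MergeLevels repeatedly merges the adjacent within-chromosome
pair with the largest Mann–Whitney p-value on member-bin ratios while
p ≥ 0.05 (threshold configurable; the underlying tool's default is not
printed anywhere, so 0.05 is declared). Merging recomputes means and reaches
a fixed point; it never increases the segment count.

Segmentation operates in ratio space by default and reports both ratio and
log2; a flag segments log2 space instead. SEG output converts to 1-based
inclusive coordinates (IGV dialect); everything internal stays 0-based
half-open.

The exome profile is a deliberately simple stand-in: per-target
library-size-normalized tumor/normal depth ratio, log2, median-centered,
zero-normal targets excluded — enough to give the clonal stage a copy-number
context for exome mutations, not an attempt at full exome CNV calling.

## CNA calls and ploidy

The copy-neutral level is the median per-bin segmentation value (even counts
use the midpoint of the central order statistics). A CNA is a maximal
within-chromosome run of bins sharing a segmentation value whose deviation
from neutral exceeds `tol` (default 1e-9, i.e. exact inequality — post-merge
segment values are treated as exact levels; a looser absolute tolerance is
available for noisy inputs). CNA length is the end of the last bin minus the
start of the first. Burden counts calls deviating at least `baseline`
(default 0.03, matching the classifier's deviation gate).

Ploidy: aneuploid iff (> 45 segments and max segment deviation from the
median > 0.03), or (25–45 segments, deviation > 0.03, and a deviating
segment spanning ≥ 10 Mb or any deviation ≥ 0.10); otherwise diploid. The
segment-count and deviation thresholds are stated rules; the numeric meaning
of "large segment" and "high value" is not printed anywhere, so 10 Mb and
0.10 are declared defaults, configurable in `PloidyThresholds`. "Not
explained by technical noise" is operationalized as the deviation gate
alone — no separate noise model.

## Somatic filter cascade

Order: caller-status retention (PASS, germline_risk) → plasma VAF ≥ 0.07
(the rule removes "< 0.07", so the boundary is retained) → matched-normal
filter (below 100X: drop if alt reads > 2; at or above 100X: drop if normal
VAF > 0.01; both boundaries retained). Depth exactly 100X uses the VAF
branch — the written rules say "less than" and "greater than" 100X, leaving
the boundary unassigned, so the assignment is declared and configurable.
Each rule depends only on a record's own fields, so the survivor set is
order-independent (asserted in tests); each dropped record carries exactly
the first-failing stage's reason code. Multi-allelic records are decomposed
per alt allele before filtering; equal-length multi-base substitutions are
counted with indels since only two buckets exist. VAFs come from allelic
depths (AD); a VCF without AD is rejected rather than guessed at.

## Clonal inference

Cellular prevalence CP = VAF·(ρ·CN + (1−ρ)·2)/(ρ·m) with purity ρ,
site total copy number CN (from the covering segment; WGS profile takes
precedence over exome, CN = round(2·ratio/neutral) floored at 1) and
multiplicity m (default 1 — multiplicity is not modeled further).
CP is clipped to [0, 1] with clipping logged. Sites with CN 0 are excluded.
Sites whose raw CP exceeds 1 by more than three binomial standard errors are
also excluded (no prevalence in [0, 1] can explain them); milder overshoot
is ordinary sampling noise and is clipped, not excluded — truly clonal
mutations overshoot about half the time, so excluding every clipped site
would discard them wholesale.

Clustering is a finite mixture over mutations with binomial read-count
likelihoods: cluster k has per-timepoint prevalence θ_kt, a site's success
probability is c_i·θ_kt with c_i = ρ·m_i/(ρ·CN_i + (1−ρ)·2), E-step
responsibilities use the full binomial log-likelihood (so low-depth sites
carry less weight), and the M-step is the depth-weighted prevalence estimate
(the exact MLE when sites share c_i, which holds for copy-neutral sites).
20 seeded restarts per K; K = argmin BIC over 1..k_max with
K·T + (K−1) parameters and N·T observations. Empty clusters are dropped
after assignment.

Tree search enumerates every parent map over the K clusters (an implicit
root bounds top-level prevalences by 1; (K+1)^(K−1) rooted forests), scoring
each by projecting the cluster centers per timepoint onto the feasible cone
{prevalence(parent) ≥ Σ children, values in [0, 1], top-level sum ≤ 1} and
summing squared projection errors. Exhaustive enumeration is the point —
there is no heuristic to validate — but it caps at K ≤ 6 by default
(16,807 trees); larger K raises an explicit error and can be unlocked by
parameter. Ties at equal error prefer the most linear (deepest) topology,
then the lexically smallest parent map: a nested chain imposes the strictest
constraints the data still satisfies, so among zero-error trees it is the
most informative summary; a star under the top clone would be reported
otherwise for every noiseless chain.

Clone (disjoint) frequency is own prevalence minus the children's sum,
clipped at 0; the constraint tolerance is 1e-6. Expansion calls flag clones
with first-timepoint frequency ≤ 0.21 (the observed range of minor,
later-expanding subclones) whose final-minus-first gain reaches 0.20; both
thresholds are parameters.

## Clinical statistics

Rank-sum tests enumerate exactly for combined n ≤ 20 without ties and
otherwise use the normal approximation with tie correction and continuity.
Kaplan–Meier and the log-rank test come from lifelines; Cox regression uses
lifelines' partial likelihood with Efron tie handling and Wald p-values
(tie handling and the 95% CI level are declared defaults — the convention is
not stated in the problem domain's reports). Zero-variance covariates are
excluded and flagged rather than passed to the optimizer.
Benjamini–Hochberg uses the standard step-up with monotonicity enforcement
(statsmodels). Proportions are reported half-up at one decimal, matching the
printed style of cohort summaries. All tests are two-sided.

## The simulator: what it emulates, what it does not

Clone trees: parents drawn uniformly from earlier clones; disjoint clone
frequencies sum to 1 per timepoint; lineage prevalences are subtree sums, so
the parent ≥ Σ children invariant holds by construction. The
`expanding_minor` scenario plants a leaf clone starting at 2–20% that rises
to ≥ (start + 0.25); `stable_dominant` keeps every clone's share jittered
around a fixed base (dominant 0.55–0.8, drift < 0.05). Trajectories are
rejection-sampled until every pair of clones is separated by ≥ 0.15 mean
absolute prevalence: the generator emulates subclones an assay can actually
report as distinct — clones closer than the read-count resolution are not
recoverable by any clustering and would only measure the generator's
willingness to create unidentifiable instances. CNA payloads live on
disjoint genomic regions across clones (inherited copy numbers never
conflict) and SNV payloads avoid CNA regions, so simulated mutation sites
are copy-neutral; multiplicity is always 1. The default genome is four
55 Mb chromosomes — 1000 bins at 220 kb — sized for test runtime, not
biology.

Bin counts: expected ratio (ρ·CN_mix + (1−ρ)·2)/2 with CN_mix the
frequency-weighted tumor copy number; counts are gamma-mixed Poisson with a
single dispersion parameter (default 0.05), matching sparse-WGS
overdispersion without per-bin GC structure. Variant counts are binomial at
fixed depths; the matched normal is clean by default (contamination
configurable to exercise the normal-filter branch).

Fragment sizes: each origin (tumor/normal) is a three-component
shifted-gamma mixture — mono-nucleosome plus di-/tri-nucleosome harmonics at
2× and 3× the mono location, weights 0.15/0.05, per-mode spread 20 bp (the
source reports no per-mode SD, so the spread is a free parameter). The 142
and 154 bp parameters are the *overall mixture means* — what a QC instrument
reports for a sample — and the mono-nucleosome location is solved from the
harmonic weights (M/(w₁ + 2w₂ + 3w₃)); fixing the mono location at the
target instead would push the sample mean ~25% high and contradict the
means the mixture is supposed to reproduce. Consequence: the simulated
mono-nucleosome mode sits near 110–125 bp, lower than the ~167 bp of real
mono-nucleosomal cfDNA — the simulator reproduces reported means and
harmonic structure, not the absolute nucleosome physics.

Clinical cohorts: exponential survival (baseline median 21 months) with the
aneuploid hazard multiplied by the ploidy effect (default 1.67, the
magnitude of the reported aneuploid/diploid survival contrast),
administrative censoring at 60 months, log-normal cfDNA mass shifted up for
aneuploid patients, and PSA weakly correlated (r ≈ 0.12) with cfDNA.

Passing tests on this simulator demonstrates recovery of planted structure
under the stated noise models. It does not demonstrate robustness to GC
waves, mappability artifacts, FFPE damage, subclonal copy number under the
mutations, purity misestimation, or non-perfect phylogenies (mutation loss,
parallel evolution) — all outside the generator by design.

## Recovery suites and problem sizes

The recovery module runs the pipeline end-to-end against planted truth, at
sizes chosen to keep the full validation under a few minutes on one CPU:

- segmentation: 100 replicates of 1000-bin profiles with steps of 0.5 at
  σ = 0.1 (5σ) at bins 300/650; success = exact breakpoints within ±1 bin;
- ploidy: 200 simulated segment-level profiles (aneuploid: 48–120 segments
  with 0.05–0.5 deviations; diploid: ≤ 17 segments with 0.01 segment-mean
  noise). The classifier is tested on its own substrate — segment profiles —
  rather than re-running CBS 200 times; the counts→CBS→classify path is
  exercised separately;
- clonal: 50 replicates of 3 clones × 3 timepoints, purity 0.6, depth 300,
  60 mutations; success = correct clone number and topology with
  clone-frequency MAE ≤ 0.05 under optimal clone matching; the planted
  expanding clone must be flagged, and 20 stable-dominant replicates must
  produce no flags;
- statistics: 1000 null cohorts (n = 200) for log-rank/rank-sum type-I
  error; 200 replicates (n = 500) of a true hazard ratio of 2 for Cox bias.

## Known limitations

- CBS p-values are pure permutation tests; no hybrid tail approximation, so
  very long chromosomes cost more than the reference implementation.
- The exome ratio profile ignores GC, target capture efficiency and allele
  fractions; it is context for the clonal stage, not a CNV caller.
- Clone trees assume a perfect phylogeny and complete mutation clustering;
  clusters below the prevalence resolution of the read depth merge, and the
  enumeration bound caps clone number at 8 (6 by default).
- Purity is an input; the bundled estimator is a crude quantile inversion
  for when nothing better exists, and is not used when purity is supplied.
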