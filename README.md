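# cfevo

Plasma whole-genome cfDNA analysis for tumor evolution studies: from binned
sparse-WGS read counts and somatic variant tables to copy-number
segmentation, aneuploidy classification, plasma–tissue concordance,
longitudinal clonal-evolution inference, and the clinical survival
statistics that accompany them — plus a synthetic-cohort simulator so the
entire pipeline can be exercised and validated without patient data.

## Who this is for

Groups analyzing liquid biopsies from cancer patients — in particular
serial plasma collections taken during therapy — who want an integrated,
testable toolchain for the computational half of a cell-free DNA (cfDNA)
workflow. The package assumes sequencing and variant calling are done
elsewhere: its inputs are per-bin read counts (or aligned-read positions),
caller output in VCF with matched-normal depths, fragment-length lists from
a QC instrument, and clinical tables.

## What it computes

**Fragment QC** (`cfevo.fragment_qc`). Fragment-size and concentration
metrics gated to 100–700 bp; a sample passes QC with ≥ 2 ng of gated mass.
Mono-nucleosomal cfDNA peaks near 150 bp and tumor-derived fragments run
shorter (≈ 142 vs 154 bp mean); the peak detector reports di-/tri-nucleosome
harmonics at 2× and 3× the primary mode.

**Copy number** (`cfevo.cnv`). Bin counts on a ~220 kb grid are normalized
to mean ratio 1 and segmented per chromosome by circular binary segmentation
(CBS): the arc (i, j] maximizing the two-sample statistic

&nbsp;&nbsp;&nbsp;&nbsp;T = max_{i<j} |S_j − S_i| / (σ̂ √(m(n−m)/n)),  m = j − i

is accepted as a split when its permutation p-value falls below
α = 10⁻⁴, followed by undo-pruning (a changepoint is removed when dropping
it raises the residual sum of squares by less than 0.05 of the current
residual) and MergeLevels (adjacent segments merge while their member-bin
ratios are rank-sum indistinguishable).

**CNA interpretation** (`cfevo.cna`). The copy-neutral state is the median
segmentation value; maximal runs of bins off that level become CNA calls
with base-pair lengths. A profile is aneuploid with > 45 segments and a
deviation > 0.03 from the median, or with 25–45 segments when a deviating
segment is large (≥ 10 Mb) or strongly deviating (≥ 0.10). Plasma–tissue
concordance uses Pearson correlation of segmentation values and
100·|A∩B|/|A∪B| for mutation sets.

**Somatic filtering** (`cfevo.variants`). Post-caller cascade: keep PASS and
germline_risk calls; drop plasma VAF < 0.07; drop variants with > 2 alt
reads in a matched normal sequenced below 100X, or normal VAF > 0.01 at
or above 100X. Survivors split into SNVs/indels; mutations with
SIFT < 0.05 and POLYPHEN > 0.85 are flagged as functionally significant.

**Clonal evolution** (`cfevo.clonal`). VAFs are normalized to cellular
prevalence,

&nbsp;&nbsp;&nbsp;&nbsp;CP = VAF · (ρ·CN + (1−ρ)·2) / (ρ·m),

with tumor purity ρ, local total copy number CN and multiplicity m.
Mutations are clustered on their prevalence trajectories by a
binomial-likelihood mixture (K chosen by BIC), and a rooted clone tree is
selected by exhaustive enumeration under the lineage constraint
prevalence(parent) ≥ Σ prevalence(children) at every timepoint. Minor clones
(first-timepoint frequency ≤ 0.21) that gain ≥ 0.20 by the final timepoint
are flagged as resistance-associated expansions.

**Clinical statistics** (`cfevo.clinstats`). Wilcoxon rank-sum,
Kaplan–Meier with the log-rank test, Cox proportional hazards (Efron ties),
Pearson correlation, Benjamini–Hochberg adjustment, and half-up one-decimal
proportion summaries.

**Simulation** (`cfevo.simulate`). Clone trees with CNA/SNV payloads under a
perfect phylogeny, purity-diluted gamma-Poisson bin counts, binomial variant
read counts over 2–6 timepoints, bimodal fragment-size mixtures with
nucleosome harmonics, and ploidy-linked exponential survival cohorts — all
deterministic given a seed.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/06_clonal_evolution.py` simulates a 3-clone patient over
three timepoints (purity 0.6, exome depth 300) and infers its clonal
structure:

```
inferred 3 clones (parent map (-1, 2, 0), fit error 0.00e+00)
clone frequencies per timepoint:
  clone 0: 0.37  0.21  0.07
  clone 1: 0.08  0.38  0.70
  clone 2: 0.51  0.38  0.20
planted truth:
  clone 0: 0.41  0.24  0.11
  clone 1: 0.51  0.38  0.20
  clone 2: 0.07  0.39  0.69

clone 1 expanded 0.08 -> 0.70: a minor subclone outgrowing the others
during therapy, the signature of treatment resistance
```

The inferred clone frequencies match the planted truth to within a few
percent (clone labels are arbitrary), the tree is recovered, and the clone
that started at 7% and expanded to ~70% under treatment is flagged.
`python examples/03_copy_number_segmentation.py` does the same for
segmentation (two planted 5σ steps recovered at bins 300/650), and
`python examples/07_clinical_statistics.py` prints the survival contrast
between aneuploid and diploid cohorts (median 10.7 vs 21.0 months,
hazard ratio ≈ 1.9 in a 300-patient simulated cohort).

A thin CLI mirrors the library for shell use:

```bash
cfevo simulate --patients 2 --clones 3 --timepoints 3 --seed 1 --outdir out/
cfevo cnv --counts out/patient1.bins.tsv --out out/p1.seg
cfevo filter --vcf out/patient1.t1.vcf --out out/p1.muts.tsv
cfevo clonal --muts out/patient1.muts.tsv --purity 0.6 --out out/p1.clones.json
```

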