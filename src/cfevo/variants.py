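"""Post-caller somatic variant filtering for plasma exome sequencing.

The caller emits candidate somatic variants with a filter status; downstream
the cascade keeps high-confidence ("PASS") and borderline-somatic
("germline_risk") calls, removes low plasma-VAF variants (< 0.07), and
removes variants supported in the matched normal (more than 2 alt reads when
the normal was sequenced below 100X, or normal VAF above 0.01 at or above
100X — the depth filters remove borderline calls that are in fact germline).
Survivors are split into SNVs and indels, and mutations with damaging
SIFT (< 0.05) and POLYPHEN (> 0.85) scores are flagged as functionally
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgument

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "CascadeResult",
    "retain_caller_status",
    "apply_plasma_vaf_filter",
    "apply_normal_filter",
    "split_variant_classes",
    "flag_functional",
    "mutation_burden",
    "run_filter_cascade",
    "read_vcf",
    "records_to_table",
]


@dataclass
class VariantRecord:
    """One somatic call (single alt allele; multi-allelics are decomposed)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    filter_status: frozenset = frozenset({"PASS"})
    plasma_depth: int = 0
    plasma_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    gene: str | None = None
    sift: float | None = None
    polyphen: float | None = None
    exonic_class: str | None = None  # synonymous | non-synonymous | other
    functional: bool | None = None
    drop_reason: str | None = None

    def __post_init__(self):
        if self.plasma_alt > self.plasma_depth or self.normal_alt > self.normal_depth:
            raise InvalidArgument("alt counts cannot exceed depths")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def plasma_vaf(self) -> float:
        return self.plasma_alt / self.plasma_depth if self.plasma_depth > 0 else float("nan")

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth > 0 else 0.0

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter cascade.

    A normal sample sequenced below ``normal_depth_cut`` uses the raw alt-read
    rule; at or above the cut it uses the VAF rule (depth exactly at the cut
    is treated as high depth).
    """

    vaf_min_plasma: float = 0.07
    normal_depth_cut: int = 100
    normal_alt_max_lowdepth: int = 2
    normal_vaf_max_highdepth: float = 0.01
    sift_max: float = 0.05
    polyphen_min: float = 0.85
    allowed_status: frozenset = frozenset({"PASS", "germline_risk"})

    def __post_init__(self):
        if not 0 <= self.vaf_min_plasma <= 1 or not 0 <= self.normal_vaf_max_highdepth <= 1:
            raise InvalidArgument("VAF thresholds must be in [0, 1]")


def _partition(records, keep_fn, reason_fn):
    kept, dropped = [], []
    for r in records:
        if keep_fn(r):
            kept.append(r)
        else:
            r.drop_reason = reason_fn(r)
            dropped.append(r)
    return kept, dropped


def retain_caller_status(records, config: FilterConfig = FilterConfig()):
    """Keep records whose caller status includes PASS or the germline-risk tag."""

    def keep(r):
        return bool(r.filter_status & config.allowed_status)

    def reason(r):
        return "missing_status" if not r.filter_status else "caller_status"

    return _partition(records, keep, reason)


def apply_plasma_vaf_filter(records, config: FilterConfig = FilterConfig()):
    """Remove variants with plasma VAF below the cutoff (boundary retained)."""

    def keep(r):
        return r.plasma_depth > 0 and r.plasma_vaf >= config.vaf_min_plasma

    def reason(r):
        return "zero_plasma_depth" if r.plasma_depth == 0 else "low_plasma_vaf"

    return _partition(records, keep, reason)


def apply_normal_filter(records, config: FilterConfig = FilterConfig()):
    """Remove variants supported in the matched normal.

    Below the depth cut: removed iff normal alt reads exceed the raw-count
    cap. At or above the cut: removed iff normal VAF exceeds the VAF cap
    (both boundaries retained).
    """

    def keep(r):
        if r.normal_depth < config.normal_depth_cut:
            return r.normal_alt <= config.normal_alt_max_lowdepth
        return r.normal_vaf <= config.normal_vaf_max_highdepth

    def reason(r):
        return (
            "normal_alt_reads"
            if r.normal_depth < config.normal_depth_cut
            else "normal_vaf"
        )

    return _partition(records, keep, reason)


def split_variant_classes(records):
    """(SNVs, indels); equal-length multi-base substitutions go with indels."""
    snvs = [r for r in records if r.variant_class == "SNV"]
    indels = [r for r in records if r.variant_class != "SNV"]
    return snvs, indels


def flag_functional(records, config: FilterConfig = FilterConfig()):
    """Set the significance flag: SIFT < sift_max AND POLYPHEN > polyphen_min.

    A record missing either score is flagged False (strict inequalities, so a
    SIFT score exactly at the cutoff is not significant).
    """
    for r in records:
        r.functional = (
            r.sift is not None
            and r.polyphen is not None
            and r.sift < config.sift_max
            and r.polyphen > config.polyphen_min
        )
    return records


def mutation_burden(records, scope: str = "all_exonic") -> int:
    """Count exonic mutations; scope 'all_exonic' or 'nonsyn_only'."""
    exonic = {"synonymous", "non-synonymous"}
    if scope == "all_exonic":
        return sum(1 for r in records if r.exonic_class in exonic)
    if scope == "nonsyn_only":
        return sum(1 for r in records if r.exonic_class == "non-synonymous")
    raise InvalidArgument(f"unknown scope {scope!r}")


@dataclass
class CascadeResult:
    survivors: list
    dropped: list
    attrition: dict = field(default_factory=dict)  # stage -> surviving count


def run_filter_cascade(records, config: FilterConfig = FilterConfig()) -> CascadeResult:
    """Caller-status retention, then plasma VAF, then matched-normal filter.

    Each rule depends only on the record's own fields, so the survivor set is
    independent of stage order; the attrition report reflects the order the
    stages are documented in. Every dropped record carries the reason of the
    first stage that failed it.
    """
    records = list(records)
    attrition = {"input": len(records)}
    dropped_all = []
    stage_fns = [
        ("caller_status", retain_caller_status),
        ("plasma_vaf", apply_plasma_vaf_filter),
        ("normal", apply_normal_filter),
    ]
    current = records
    for name, fn in stage_fns:
        current, dropped = fn(current, config)
        attrition[name] = len(current)
        dropped_all.extend(dropped)
    return CascadeResult(survivors=current, dropped=dropped_all, attrition=attrition)


# ---------------------------------------------------------------------------
# VCF input / tabular output
# ---------------------------------------------------------------------------


def read_vcf(
    path: str,
    plasma_sample: str = "PLASMA",
    normal_sample: str = "NORMAL",
    gene_key: str = "GENE",
    sift_key: str = "SIFT",
    polyphen_key: str = "POLYPHEN",
    exonic_key: str = "EXONIC_CLASS",
) -> list[VariantRecord]:
    """Load somatic calls from a VCF with plasma and matched-normal columns.

    Allelic depths come from the AD FORMAT field (depth = sum over alleles);
    multi-allelic records are decomposed into one record per alt allele.
    Annotations are read from the named INFO keys when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    for s in (plasma_sample, normal_sample):
        if s not in samples:
            raise InvalidArgument(f"sample {s!r} not in VCF ({samples})")
    ip, inorm = samples.index(plasma_sample), samples.index(normal_sample)
    out = []
    for v in vcf:
        status = frozenset((v.FILTER or "PASS").split(";"))
        ad = v.format("AD")
        if ad is None:
            raise InvalidArgument(f"record {v.CHROM}:{v.POS} lacks AD field")
        ad = np.maximum(np.asarray(ad, dtype=np.int64), 0)
        for ai, alt in enumerate(v.ALT):
            out.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    filter_status=status,
                    plasma_depth=int(ad[ip].sum()),
                    plasma_alt=int(ad[ip][ai + 1]),
                    normal_depth=int(ad[inorm].sum()),
                    normal_alt=int(ad[inorm][ai + 1]),
                    gene=v.INFO.get(gene_key),
                    sift=_maybe_float(v.INFO.get(sift_key)),
                    polyphen=_maybe_float(v.INFO.get(polyphen_key)),
                    exonic_class=v.INFO.get(exonic_key),
                )
            )
    return out


def _maybe_float(x):
    return None if x is None else float(x)


def records_to_table(records) -> pd.DataFrame:
    """Flatten records into a mutation table (one row per alt allele)."""
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class,
                "plasma_depth": r.plasma_depth,
                "plasma_alt": r.plasma_alt,
                "plasma_vaf": r.plasma_vaf,
                "normal_depth": r.normal_depth,
                "normal_alt": r.normal_alt,
                "gene": r.gene,
                "sift": r.sift,
                "polyphen": r.polyphen,
                "exonic_class": r.exonic_class,
                "functional": r.functional,
                "drop_reason": r.drop_reason,
            }
        )
    return pd.DataFrame(rows)
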