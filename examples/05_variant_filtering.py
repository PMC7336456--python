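"""The somatic variant filter cascade on an engineered VCF.

Candidate calls are kept when the caller marked them PASS or germline_risk,
their plasma VAF is at least 0.07, and the matched normal does not support
them (at most 2 alt reads below 100X; normal VAF at most 0.01 otherwise).
Survivors split into SNVs/indels and damaging mutations are flagged by
SIFT < 0.05 and POLYPHEN > 0.85."""

import tempfile
from pathlib import Path

from cfevo.io import write_vcf
from cfevo.recovery import engineered_filter_table
from cfevo.variants import (
    flag_functional,
    mutation_burden,
    read_vcf,
    run_filter_cascade,
    split_variant_classes,
)

table = engineered_filter_table()
with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "demo.vcf"
    write_vcf(table, vcf)
    records = read_vcf(str(vcf))

result = run_filter_cascade(records)
print("attrition through the cascade:", result.attrition)
for rec in result.dropped[:4]:
    print(f"  dropped {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}: {rec.drop_reason}")

snvs, indels = split_variant_classes(result.survivors)
flag_functional(result.survivors)
significant = [r for r in result.survivors if r.functional]
print(f"\nsurvivors: {len(snvs)} SNVs + {len(indels)} indels; "
      f"exonic burden {mutation_burden(result.survivors, 'all_exonic')}, "
      f"non-synonymous {mutation_burden(result.survivors, 'nonsyn_only')}")
print(f"functionally significant (damaging SIFT and POLYPHEN): "
      f"{[f'{r.gene}' for r in significant]}")
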