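"""Clinical statistics on a simulated cohort.

Kaplan-Meier/log-rank survival by ploidy, Cox proportional hazards with the
aneuploid indicator, a rank-sum comparison of cfDNA mass between ploidy
groups, Benjamini-Hochberg adjustment, and the cohort proportion summary."""

import numpy as np

from cfevo.clinstats import (
    bh_adjust,
    cox_ph,
    km_logrank,
    pearson_r,
    proportion_summary,
    wilcoxon_rank_sum,
)
from cfevo.simulate import simulate_cohort_clinical

cohort = simulate_cohort_clinical(300, ploidy_effect=1.67, seed=9)
cohort["aneuploid"] = (cohort["ploidy"] == "aneuploid").astype(int)

res, curves = km_logrank(cohort, "ploidy", "survival_months", "event")
med = {g: c.loc[c["survival"] <= 0.5, "time"].min() for g, c in curves.items()}
print(f"log-rank by ploidy: chi2 {res.statistic:.2f}, p {res.p_value:.2g}")
print(f"median survival: diploid {med['diploid']:.1f} vs "
      f"aneuploid {med['aneuploid']:.1f} months")

cox = cox_ph(cohort, ["aneuploid"], mode="univariate",
             time_field="survival_months", event_field="event").iloc[0]
print(f"Cox hazard ratio for aneuploidy {cox['hazard_ratio']:.2f} "
      f"[{cox['ci_lower']:.2f}, {cox['ci_upper']:.2f}], p {cox['p']:.2g}")

wx = wilcoxon_rank_sum(
    cohort.loc[cohort.aneuploid == 1, "cfdna_ng"],
    cohort.loc[cohort.aneuploid == 0, "cfdna_ng"],
)
print(f"cfDNA mass aneuploid vs diploid: rank-sum p {wx.p_value:.2g} "
      "(aneuploid patients shed more tumor DNA)")

corr = pearson_r(cohort["psa_ng_ml"], cohort["cfdna_ng"])
print(f"PSA vs cfDNA correlation r {corr.statistic:.2f}, p {corr.p_value:.2g} "
      "(weak by design)")

adj = bh_adjust([res.p_value, cox["p"], wx.p_value, corr.p_value])
print("BH-adjusted p-values:", np.round(adj, 4).tolist())

passed = int((cohort["cfdna_ng"] >= 2.0).sum())
print(f"patients with >= 2 ng cfDNA: {passed}/300 = "
      f"{proportion_summary(passed, 300)}% would pass library QC")
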