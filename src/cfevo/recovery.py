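"""Seeded recovery suites: the pipeline run end-to-end against planted truth.

Each function generates synthetic inputs with the simulator, runs the
corresponding pipeline stage, and scores recovery of the planted structure
(breakpoints, ploidy labels, clone trees and frequencies, statistical
calibration). They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import clonal, cna, cnv, simulate
from .clinstats import cox_ph, km_logrank, wilcoxon_rank_sum

__all__ = [
    "engineered_filter_table",
    "segmentation_recovery",
    "ploidy_recovery",
    "clonal_recovery",
    "stable_scenario_false_flags",
    "logrank_wilcoxon_type1",
    "cox_loghr_bias",
]


def engineered_filter_table() -> pd.DataFrame:
    """20 variant records spanning every branch of the somatic filter cascade:
    the plasma-VAF boundary (0.06 vs 0.07, 0.069 vs 0.070), both matched-normal
    depth branches with their boundaries (80X with 2 vs 3 alt reads, 200X with
    normal VAF 0.01 vs 0.015, depth exactly 100), caller status tags, the
    SNV/indel/MNV split, and the SIFT/POLYPHEN significance cutoffs."""
    rows = [
        (100, "A", "G", "PASS", 6, 100, 0, 80, None, None, "non-synonymous"),
        (200, "A", "G", "PASS", 7, 100, 0, 80, None, None, "non-synonymous"),
        (300, "C", "T", "germline_risk", 20, 100, 3, 80, None, None, "synonymous"),
        (400, "C", "T", "germline_risk", 20, 100, 2, 80, None, None, "synonymous"),
        (500, "G", "A", "clustered_events", 50, 100, 0, 80, None, None, "other"),
        (600, "G", "A", "PASS", 50, 100, 3, 200, None, None, "non-synonymous"),
        (700, "G", "A", "PASS", 50, 100, 2, 200, None, None, "non-synonymous"),
        (800, "T", "C", "PASS", 0, 100, 0, 80, None, None, "synonymous"),
        (900, "T", "C", "PASS", 30, 100, 1, 100, None, None, "non-synonymous"),
        (1000, "T", "C", "PASS", 30, 100, 2, 100, None, None, "non-synonymous"),
        (1100, "A", "C", "germline_risk;clustered_events", 30, 100, 0, 80, None, None, "other"),
        (1200, "AT", "A", "PASS", 30, 100, 0, 80, None, None, "non-synonymous"),
        (1300, "A", "AT", "PASS", 30, 100, 0, 80, None, None, "non-synonymous"),
        (1400, "AT", "GC", "PASS", 30, 100, 0, 80, None, None, "other"),
        (1500, "C", "G", "PASS", 69, 1000, 0, 80, None, None, "synonymous"),
        (1600, "C", "G", "PASS", 70, 1000, 0, 80, None, None, "synonymous"),
        (1700, "G", "T", "PASS", 30, 100, 3, 99, None, None, "non-synonymous"),
        (1800, "G", "T", "PASS", 30, 100, 2, 99, None, None, "non-synonymous"),
        (1900, "A", "T", "PASS", 40, 100, 0, 80, 0.01, 0.95, "non-synonymous"),
        (2000, "A", "T", "PASS", 40, 100, 0, 80, 0.05, 0.95, "non-synonymous"),
    ]
    return pd.DataFrame(
        [
            {
                "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "filter": filt,
                "alt_t1": pa, "depth_t1": pdep, "normal_alt": na, "normal_depth": nd,
                "gene": f"GENE{pos}", "sift": sift, "polyphen": poly,
                "exonic_class": exonic,
            }
            for pos, ref, alt, filt, pa, pdep, na, nd, sift, poly, exonic in rows
        ]
    )


def segmentation_recovery(
    n_replicates: int = 100,
    n_bins: int = 1000,
    breakpoints: tuple = (300, 650),
    step: float = 0.5,
    sigma: float = 0.1,
    depth: float = 50.0,
    seed: int = 0,
) -> dict:
    """CBS + MergeLevels breakpoint recovery on planted-step profiles.

    Each replicate plants alternating-direction steps of ``step`` (>= 5 sigma
    at the defaults) on a 1000-bin chromosome; a success recovers exactly the
    planted changepoints, each within one bin.
    """
    grid = cnv.BinGrid.uniform({"chr1": 220_000 * n_bins}, 220_000)
    recovered = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        x = np.ones(n_bins)
        for i, bp in enumerate(breakpoints):
            x[bp:] += step * (1 if i % 2 == 0 else -1)
        raw = np.maximum((x + rng.normal(0, sigma, n_bins)) * depth, 0).astype(int)
        counts = cnv.normalize(cnv.BinCounts(grid=grid, raw=raw))
        prof = cnv.merge_levels(
            cnv.cbs_segment(counts, cnv.CBSParams(seed=seed + rep)), counts
        )
        cps = sorted(prof.segments["start_bin"].to_numpy()[1:])
        ok = len(cps) == len(breakpoints) and all(
            abs(c - b) <= 1 for c, b in zip(cps, sorted(breakpoints))
        )
        recovered += ok
    return {"rate": recovered / n_replicates, "n": n_replicates}


def ploidy_recovery(n_samples: int = 200, seed: int = 0) -> dict:
    """Planted aneuploid/diploid label recovery on simulated segment profiles."""
    correct = 0
    for i in range(n_samples):
        truth = i % 2 == 0
        prof = simulate.simulate_segment_means(truth, seed=seed + i)
        call = cna.classify_ploidy(prof)
        correct += call.label == ("aneuploid" if truth else "diploid")
    return {"rate": correct / n_samples, "n": n_samples}


def _match_to_truth(freq_inf: np.ndarray, freq_true: np.ndarray):
    cost = np.abs(freq_inf[:, None, :] - freq_true[None, :, :]).mean(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return dict(zip(rows, cols)), float(cost[rows, cols].mean())


def _topology_matches(model, tree, mapping) -> bool:
    true_parent = {c.clone_id: c.parent_id for c in tree.clones}
    for i in range(model.k):
        p = model.parent[i]
        tp = true_parent[mapping[i]]
        if p == -1:
            if tp is not None:
                return False
        elif tp != mapping.get(p):
            return False
    return True


def clonal_recovery(
    n_replicates: int = 50,
    n_clones: int = 3,
    n_timepoints: int = 3,
    purity: float = 0.6,
    depth: int = 300,
    n_snv_per_clone: int = 20,
    seed: int = 0,
) -> dict:
    """End-to-end clonal inference against planted trees.

    Simulates expanding-minor patients (60 mutations at the defaults), runs
    prevalence normalization -> clustering -> tree search, and scores: joint
    recovery (correct clone number and topology with clone-frequency MAE
    <= 0.05), the mean MAE itself, and whether the planted expanding minor
    clone is flagged by the expansion detector.
    """
    joint = 0
    expander_flagged = 0
    maes = []
    tps = list(range(1, n_timepoints + 1))
    for rep in range(n_replicates):
        tree = simulate.simulate_clone_tree(
            n_clones, n_timepoints, "expanding_minor", seed=seed + rep,
            n_snv_per_clone=n_snv_per_clone,
        )
        tab = simulate.simulate_variants(
            tree, [purity] * n_timepoints, depth_plasma=depth, seed=seed + rep + 10_000
        )
        keys = list(zip(tab.chrom, tab.pos, tab.ref, tab.alt))
        prev = clonal.build_prevalence_matrix(
            keys,
            tab[[f"alt_t{t}" for t in tps]].to_numpy(),
            tab[[f"depth_t{t}" for t in tps]].to_numpy(),
            [purity] * n_timepoints,
            cn_per_site=tab.cn.to_numpy(),
        )
        model = clonal.infer_clonal_structure(prev, k_max=6, seed=seed + rep)
        freq_true = tree.clone_frequency_matrix()
        if model.k == n_clones:
            freq_inf = clonal.clone_frequencies(model)
            mapping, mae = _match_to_truth(freq_inf, freq_true)
            maes.append(mae)
            if _topology_matches(model, tree, mapping) and mae <= 0.05:
                joint += 1
            calls = clonal.detect_expanding_clones(model)
            expander_inf = next(
                (i for i, c in mapping.items() if c == n_clones - 1), None
            )
            if expander_inf is not None and calls[expander_inf].flagged:
                expander_flagged += 1
    return {
        "joint_rate": joint / n_replicates,
        "mean_mae": float(np.mean(maes)) if maes else float("nan"),
        "expander_flag_rate": expander_flagged / n_replicates,
        "n": n_replicates,
    }


def stable_scenario_false_flags(
    n_replicates: int = 20,
    n_clones: int = 3,
    n_timepoints: int = 3,
    purity: float = 0.6,
    depth: int = 300,
    seed: int = 0,
) -> dict:
    """Expansion flags raised on stable-dominant patients (should be none)."""
    flags = 0
    tps = list(range(1, n_timepoints + 1))
    for rep in range(n_replicates):
        tree = simulate.simulate_clone_tree(
            n_clones, n_timepoints, "stable_dominant", seed=seed + rep
        )
        tab = simulate.simulate_variants(
            tree, [purity] * n_timepoints, depth_plasma=depth, seed=seed + rep + 10_000
        )
        keys = list(zip(tab.chrom, tab.pos, tab.ref, tab.alt))
        prev = clonal.build_prevalence_matrix(
            keys,
            tab[[f"alt_t{t}" for t in tps]].to_numpy(),
            tab[[f"depth_t{t}" for t in tps]].to_numpy(),
            [purity] * n_timepoints,
            cn_per_site=tab.cn.to_numpy(),
        )
        model = clonal.infer_clonal_structure(prev, k_max=6, seed=seed + rep)
        flags += sum(c.flagged for c in clonal.detect_expanding_clones(model))
    return {"false_flags": flags, "n": n_replicates}


def logrank_wilcoxon_type1(
    n_cohorts: int = 1000, n_patients: int = 200, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the log-rank and rank-sum tests on null cohorts.

    Survival is simulated with no ploidy effect, so group labels carry no
    hazard information; the rank-sum test compares PSA (independent of ploidy
    by construction) between the ploidy groups.
    """
    rej_lr = rej_wx = 0
    for i in range(n_cohorts):
        df = simulate.simulate_cohort_clinical(n_patients, ploidy_effect=1.0, seed=seed + i)
        res, _ = km_logrank(df, "ploidy", "survival_months", "event")
        rej_lr += res.p_value < alpha
        x = df.loc[df.ploidy == "aneuploid", "psa_ng_ml"]
        y = df.loc[df.ploidy == "diploid", "psa_ng_ml"]
        rej_wx += wilcoxon_rank_sum(x, y).p_value < alpha
    return {
        "logrank_rate": rej_lr / n_cohorts,
        "wilcoxon_rate": rej_wx / n_cohorts,
        "n": n_cohorts,
    }


def cox_loghr_bias(
    n_replicates: int = 200, n_patients: int = 500, hazard_ratio: float = 2.0, seed: int = 0
) -> dict:
    """Bias of the Cox log-hazard-ratio estimate on two-group exponential data."""
    coefs = []
    for i in range(n_replicates):
        df = simulate.simulate_cohort_clinical(
            n_patients, ploidy_effect=hazard_ratio, seed=seed + i
        )
        df["aneuploid"] = (df["ploidy"] == "aneuploid").astype(int)
        out = cox_ph(df, ["aneuploid"], mode="univariate",
                     time_field="survival_months", event_field="event")
        coefs.append(float(out["coef"].iloc[0]))
    return {
        "mean_coef": float(np.mean(coefs)),
        "bias": float(np.mean(coefs) - np.log(hazard_ratio)),
        "n": n_replicates,
    }
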