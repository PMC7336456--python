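"""Clinical statistics: rank-sum comparisons, Kaplan-Meier/log-rank survival,
Cox proportional hazards, Pearson correlation, Benjamini-Hochberg adjustment,
and the cohort proportion summaries reported alongside them."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientData, InvalidArgument

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "km_logrank",
    "cox_ph",
    "bh_adjust",
    "pearson_r",
    "proportion_summary",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample is small (n <= 20) without
    ties; normal approximation with tie correction and continuity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgument("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_rank_sum_{method}",
        n_per_group=(x.size, y.size),
    )


def km_logrank(
    records: pd.DataFrame,
    group_field: str = "group",
    time_field: str = "time",
    event_field: str = "event",
) -> tuple[TestResult, dict]:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns (test result, {group: curve DataFrame}); curves carry the
    product-limit estimate with at-risk counts and 95% CI. Needs at least two
    groups and one event.
    """
    groups = records[group_field].unique()
    if len(groups) < 2:
        raise InvalidArgument("need >= 2 groups for the log-rank test")
    if records[event_field].sum() < 1:
        raise InsufficientData("no events observed; log-rank test undefined")
    if len(groups) == 2:
        a = records[records[group_field] == groups[0]]
        b = records[records[group_field] == groups[1]]
        res = logrank_test(
            a[time_field], b[time_field], a[event_field], b[event_field]
        )
    else:
        res = multivariate_logrank_test(
            records[time_field], records[group_field], records[event_field]
        )
    curves = {}
    for g in groups:
        sub = records[records[group_field] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_field], sub[event_field], label=str(g))
        tbl = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
                "ci_lower": kmf.confidence_interval_.iloc[:, 0].to_numpy(),
                "ci_upper": kmf.confidence_interval_.iloc[:, 1].to_numpy(),
            }
        ).reset_index(drop=True)
        curves[g] = curve
    n_per_group = tuple(int((records[group_field] == g).sum()) for g in groups)
    return (
        TestResult(
            statistic=float(res.test_statistic),
            p_value=float(res.p_value),
            method="logrank",
            n_per_group=n_per_group,
        ),
        curves,
    )


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    mode: str = "multivariate",
    time_field: str = "time",
    event_field: str = "event",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling, Wald p).

    ``mode`` 'univariate' fits each covariate alone; 'multivariate' fits them
    jointly. Zero-variance covariates are excluded and flagged in the output.
    Returns one row per covariate: coef, hazard_ratio, CI bounds, p, excluded.
    """
    if mode not in ("univariate", "multivariate"):
        raise InvalidArgument("mode must be univariate or multivariate")
    usable, excluded = [], []
    for c in covariates:
        if records[c].nunique() <= 1:
            excluded.append(c)
        else:
            usable.append(c)
    n_events = int(records[event_field].sum())
    if n_events < len(usable) + 1:
        raise InsufficientData("too few events for the number of covariates")
    rows = []
    groups = [[c] for c in usable] if mode == "univariate" else ([usable] if usable else [])
    for grp in groups:
        cph = CoxPHFitter(alpha=alpha)
        cph.fit(
            records[[time_field, event_field] + grp],
            duration_col=time_field,
            event_col=event_field,
        )
        s = cph.summary
        for c in grp:
            rows.append(
                {
                    "covariate": c,
                    "coef": float(s.loc[c, "coef"]),
                    "hazard_ratio": float(s.loc[c, "exp(coef)"]),
                    "ci_lower": float(np.exp(s.loc[c, f"coef lower {100 * (1 - alpha):g}%"])),
                    "ci_upper": float(np.exp(s.loc[c, f"coef upper {100 * (1 - alpha):g}%"])),
                    "p": float(s.loc[c, "p"]),
                    "excluded": False,
                }
            )
    for c in excluded:
        rows.append(
            {
                "covariate": c,
                "coef": np.nan,
                "hazard_ratio": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "p": np.nan,
                "excluded": True,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidArgument("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgument("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(float("nan"), float("nan"), "pearson_zero_variance", (x.size,))
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson", (x.size,))


def proportion_summary(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, half-up rounding (e.g. 130/233 -> 55.8)."""
    if denominator <= 0:
        raise InvalidArgument("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise InvalidArgument("need 0 <= numerator <= denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
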