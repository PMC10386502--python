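"""Cohort-characteristics tables (the classic clinical "Table 1").

Continuous variables are summarized as mean (SD) per outcome group with a
Welch (unequal-variance) two-sample t-test between groups; categorical
variables as count (%) with a Pearson chi-square test (no continuity
correction).  Pooled-cohort columns can be reconstructed purely from
subgroup summaries: the pooled mean is the n-weighted average of subgroup
means, the pooled SD follows the combined-variance identity, and pooled
percentages are combined counts over combined n — so a printed table's
internal arithmetic can be checked without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    """Mean/SD/n of one continuous variable in one group."""

    mean: float
    sd: float
    n: int


def welch_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
            n2: int) -> tuple[float, float, float]:
    """Welch's t from group summaries: (t, Satterthwaite df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be nonnegative and not both zero")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=False)
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df), float(p)


def chi_square(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x c contingency table, no Yates correction."""
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x c contingency table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pooled_mean_sd(groups: list[GroupSummary]) -> tuple[float, float, int]:
    """Pooled mean and SD from subgroup (mean, SD, n) summaries.

    Uses the exact combined-variance identity, so it matches the direct SD
    of the concatenated raw data (with n-1 denominators throughout).
    """
    n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n
    ss = sum((g.n - 1) * g.sd ** 2 + g.n * (g.mean - mean) ** 2 for g in groups)
    sd = np.sqrt(ss / (n - 1))
    return float(mean), float(sd), int(n)


def pooled_percentage(counts: list[int], ns: list[int]) -> float:
    """Combined count over combined n, as a percentage."""
    return 100.0 * sum(counts) / sum(ns)


def cohort_summary(meta, continuous: dict[str, np.ndarray] | None = None,
                   categorical: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Build a Table-1-style cohort summary from raw per-sample data.

    ``meta`` is a :class:`~metaborank.containers.SampleMetadata`; age and
    sex are always included, extra continuous/categorical columns may be
    supplied as arrays aligned to the samples.  Returns a tidy frame with
    one row per variable (or categorical level): pooled and per-group
    summaries plus the between-group p-value (Welch t for continuous,
    chi-square for categorical, one test per variable).
    """
    y = meta.outcome
    continuous = dict(continuous or {})
    categorical = dict(categorical or {})
    continuous.setdefault("age", meta.age)
    categorical.setdefault("sex", meta.table["sex"].to_numpy())

    rows = []
    g1, g0 = y == 1, y == 0
    rows.append({"variable": "n", "level": "", "all": float(len(y)),
                 "group1": float(g1.sum()), "group0": float(g0.sum()),
                 "p_value": np.nan, "kind": "count"})
    for name, x in continuous.items():
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x)
        s1 = GroupSummary(x[g1 & ok].mean(), x[g1 & ok].std(ddof=1), int((g1 & ok).sum()))
        s0 = GroupSummary(x[g0 & ok].mean(), x[g0 & ok].std(ddof=1), int((g0 & ok).sum()))
        mean, sd, _ = pooled_mean_sd([s1, s0])
        _, _, p = welch_t(s1.mean, s1.sd, s1.n, s0.mean, s0.sd, s0.n)
        rows.append({"variable": name, "level": "mean_sd", "all": mean,
                     "all_sd": sd, "group1": s1.mean, "group1_sd": s1.sd,
                     "group0": s0.mean, "group0_sd": s0.sd, "p_value": p,
                     "kind": "continuous"})
    for name, x in categorical.items():
        x = pd.Series(x).astype(str).to_numpy()
        levels = sorted(pd.unique(x))
        table = np.array([[int(((y == g) & (x == lv)).sum()) for lv in levels]
                          for g in (1, 0)])
        if len(levels) > 1:
            _, _, p = chi_square(table)
        else:
            p = np.nan
        for j, lv in enumerate(levels):
            c1, c0 = int(table[0, j]), int(table[1, j])
            rows.append({
                "variable": name, "level": lv,
                "all": pooled_percentage([c1, c0], [int(g1.sum()), int(g0.sum())]),
                "all_count": c1 + c0,
                "group1": 100.0 * c1 / g1.sum(), "group1_count": c1,
                "group0": 100.0 * c0 / g0.sum(), "group0_count": c0,
                "p_value": p if j == 0 else np.nan, "kind": "categorical"})
    return pd.DataFrame(rows)
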