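"""Group-level lateralization statistics.

One-sample t-tests per indicator (is the group reliably lateralized?),
Welch two-sample tests of left- vs right-handers on session-averaged LIs
with Bonferroni correction, Shapiro-Wilk normality checks per
task/session/group, pairwise-complete Pearson correlation matrices, and
split-half (odd/even trial) reliability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .li import DEFAULT_POI, compute_li
from .types import INDICATORS, TASKS, LITable


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def one_sample_tests(table: LITable, group: str) -> pd.DataFrame:
    """Two-sided one-sample t-test of mean LI != 0 per indicator.

    Star coding: * p<0.05, ** p<0.01, *** p<0.001. Indicators with fewer
    than 3 observed values are marked not computable (NaN statistics).
    """
    vals = table.group_values(group)
    rows = []
    for ind in INDICATORS:
        x = vals[ind].dropna().to_numpy()
        if len(x) < 3 or np.allclose(x, x[0]):
            rows.append({"indicator": ind, "n": len(x), "mean": np.nan, "t": np.nan,
                         "df": np.nan, "p": np.nan, "stars": "", "computable": False})
            continue
        res = sps.ttest_1samp(x, 0.0)
        rows.append({
            "indicator": ind, "n": len(x), "mean": float(np.mean(x)),
            "t": float(res.statistic), "df": len(x) - 1, "p": float(res.pvalue),
            "stars": _stars(res.pvalue), "computable": True,
        })
    return pd.DataFrame(rows).set_index("indicator")


def welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    """Welch-Satterthwaite fractional degrees of freedom."""
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def handedness_comparison(table: LITable, family_alpha: float = 0.05) -> pd.DataFrame:
    """Per-task Welch t-tests of left- vs right-handers on session-averaged
    LIs, at Bonferroni alpha = family_alpha / 6.

    Session averaging ignores missing cells (a participant with one session
    contributes that session's value alone).
    """
    means = table.session_means()
    groups = table.groups
    left = means[groups == "left"]
    right = means[groups == "right"]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("both handedness groups must be present")
    alpha = family_alpha / len(TASKS)
    rows = []
    for t in TASKS:
        x = left[t].dropna().to_numpy()
        y = right[t].dropna().to_numpy()
        res = sps.ttest_ind(x, y, equal_var=False)
        df = welch_df(x.var(ddof=1), len(x), y.var(ddof=1), len(y))
        rows.append({
            "task": t, "n_left": len(x), "n_right": len(y),
            "mean_left": float(x.mean()), "mean_right": float(y.mean()),
            "t": float(res.statistic), "df": float(df), "p": float(res.pvalue),
            "bonferroni_alpha": alpha, "family_size": len(TASKS),
            "significant": bool(res.pvalue < alpha),
        })
    return pd.DataFrame(rows).set_index("task")


def normality_tests(table: LITable) -> pd.DataFrame:
    """Shapiro-Wilk W and p per task/session/group (24 tests for a
    two-group table). Constant or too-small samples are not computable."""
    rows = []
    for group in sorted(table.groups.unique()):
        vals = table.group_values(group)
        for t in TASKS:
            for s in (1, 2):
                x = vals[f"{t}{s}"].dropna().to_numpy()
                if len(x) < 3 or np.allclose(x, x[0]):
                    rows.append({"group": group, "task": t, "session": s,
                                 "W": np.nan, "p": np.nan, "computable": False})
                    continue
                res = sps.shapiro(x)
                rows.append({"group": group, "task": t, "session": s,
                             "W": float(res.statistic), "p": float(res.pvalue),
                             "computable": True})
    return pd.DataFrame(rows)


def correlation_matrix(table: LITable, group: str) -> pd.DataFrame:
    """12x12 Pearson correlation matrix with pairwise deletion of missing
    cells (each pair uses its complete observations; >=3 required)."""
    vals = table.group_values(group)
    corr = vals.corr(method="pearson", min_periods=3)
    return corr.loc[INDICATORS, INDICATORS]


def split_half_reliability(
    epoch_sets: dict, poi: tuple[float, float] = DEFAULT_POI, min_trials: int = 4
) -> pd.DataFrame:
    """Odd/even-trial split-half correlation per task.

    ``epoch_sets`` maps ``(subject, indicator)`` to a preprocessed
    EpochSet. For each participant/indicator the LI is computed separately
    from odd- and even-positioned *usable* trials; participants with fewer
    than ``min_trials`` usable trials are skipped. Returns per-indicator
    Pearson correlations across participants (NaN if < 3 participants).
    """
    odd: dict = {}
    even: dict = {}
    for (subj, ind), ep in epoch_sets.items():
        usable = np.nonzero(ep.usable)[0]
        if len(usable) < min_trials:
            continue
        odd_est = compute_li(ep, poi=poi, trial_subset=usable[1::2])
        even_est = compute_li(ep, poi=poi, trial_subset=usable[0::2])
        odd.setdefault(ind, {})[subj] = odd_est.li
        even.setdefault(ind, {})[subj] = even_est.li
    rows = []
    for ind in sorted(odd):
        subjects = sorted(odd[ind])
        x = np.array([odd[ind][s] for s in subjects])
        y = np.array([even[ind][s] for s in subjects])
        if len(subjects) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"indicator": ind, "n": len(subjects), "r": np.nan})
            continue
        r, _ = sps.pearsonr(x, y)
        rows.append({"indicator": ind, "n": len(subjects), "r": float(r)})
    return pd.DataFrame(rows).set_index("indicator")


def stat_report(table: LITable) -> dict:
    """Flat JSON-serializable report covering the full battery."""
    report: dict = {"schema_version": 1}
    for group in sorted(table.groups.unique()):
        report[f"one_sample_{group}"] = (
            one_sample_tests(table, group).reset_index().to_dict(orient="records")
        )
        report[f"correlations_{group}"] = correlation_matrix(table, group).round(6).to_dict()
    if set(table.groups.unique()) == {"left", "right"}:
        report["handedness"] = handedness_comparison(table).reset_index().to_dict(orient="records")
    report["normality"] = normality_tests(table).to_dict(orient="records")
    return report
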