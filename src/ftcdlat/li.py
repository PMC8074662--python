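"""Laterality-index computation and data-quality exclusion rules.

The LI for one participant/task/session is the mean of the averaged
left-minus-right difference waveform over the period of interest (the mean
method, not the peak method, which can induce artificial bimodality in LI
distributions). Trial-to-trial variability yields a standard error and a
t-based 95% confidence interval, from which the reliably-lateralized flag
is derived (left if the CI excludes zero from above, right from below).

Quality rules: cells whose trial-wise SE is unusually high under the
Hoaglin-Iglewicz quartile screen (above Q3 + 2.2*IQR of the task's SE
distribution) are dropped; cells with fewer than 10 usable trials are
dropped; and a participant with more than one task excluded for quality
reasons is removed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import INDICATORS, TASKS, EpochSet, LITable

#: Default period of interest (s, peri-stimulus). The task occupies 3-23 s
#: and the blood-flow response lags onset by roughly 3 s.
DEFAULT_POI = (6.0, 23.0)
HOAGLIN_IGLEWICZ_G = 2.2
MIN_TRIALS = 10


@dataclass
class LIEstimate:
    """Laterality index with trial-wise uncertainty for one task/session."""

    li: float
    se: float
    ci: tuple[float, float]
    n_trials: int
    poi: tuple[float, float]
    flag: str  # 'left' | 'right' | 'none'
    reason: Optional[str] = None  # set when the cell is missing
    per_trial: Optional[np.ndarray] = None

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.li)


def compute_li(
    epochs: EpochSet,
    poi: tuple[float, float] = DEFAULT_POI,
    trial_subset: Optional[np.ndarray] = None,
) -> LIEstimate:
    """LI from usable trials: mean left-minus-right difference in the POI.

    The averaged-waveform mean equals the mean of per-trial POI means
    (equal trial weighting); the SE is the SD of the per-trial means over
    sqrt(n), and the CI uses Student's t with n-1 df. ``trial_subset``
    restricts to a subset of trial indices (used for split-half
    reliability); only usable trials are ever included.
    """
    if poi[0] < epochs.times[0] or poi[1] > epochs.times[-1]:
        raise ValueError("period of interest lies outside the epoch window")
    usable = np.nonzero(epochs.usable)[0]
    if trial_subset is not None:
        usable = np.intersect1d(usable, np.asarray(trial_subset))
    n = len(usable)
    if n == 0:
        return LIEstimate(
            li=np.nan, se=np.nan, ci=(np.nan, np.nan), n_trials=0, poi=poi,
            flag="none", reason="no-usable-trials",
        )
    mask = (epochs.times >= poi[0]) & (epochs.times <= poi[1])
    diff = epochs.left[usable][:, mask] - epochs.right[usable][:, mask]
    per_trial = diff.mean(axis=1)
    li = float(per_trial.mean())
    if n > 1:
        se = float(per_trial.std(ddof=1) / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        ci = (li - tcrit * se, li + tcrit * se)
    else:
        se = np.nan
        ci = (-np.inf, np.inf)
    if ci[0] > 0:
        flag = "left"
    elif ci[1] < 0:
        flag = "right"
    else:
        flag = "none"
    return LIEstimate(li=li, se=se, ci=ci, n_trials=n, poi=poi, flag=flag, per_trial=per_trial)


def build_li_table(estimates: dict, meta: pd.DataFrame) -> LITable:
    """Assemble an LITable from ``{(subject, indicator): LIEstimate}`` plus a
    subject-indexed metadata frame with ``group`` and ``site`` columns."""
    rows, counts, reasons = {}, {}, {}
    for subj in meta.index:
        rows[subj] = {"group": meta.loc[subj, "group"], "site": meta.loc[subj, "site"]}
        counts[subj] = {}
        for ind in INDICATORS:
            est = estimates.get((subj, ind))
            if est is None or est.missing:
                rows[subj][ind] = np.nan
                counts[subj][ind] = 0 if est is None else est.n_trials
                reasons[(subj, ind)] = est.reason if est is not None else "not-recorded"
            else:
                rows[subj][ind] = est.li
                counts[subj][ind] = est.n_trials
    data = pd.DataFrame.from_dict(rows, orient="index")
    cnt = pd.DataFrame.from_dict(counts, orient="index")
    return LITable(data, counts=cnt, reasons=reasons)


def se_outlier_screen(
    se_table: pd.DataFrame, g: float = HOAGLIN_IGLEWICZ_G, min_values: int = 8
) -> pd.DataFrame:
    """Hoaglin-Iglewicz screen on trial-wise SEs, per indicator column.

    Returns a boolean frame marking cells whose SE exceeds
    Q3 + g*(Q3 - Q1) of that indicator's SE distribution (one-sided: only
    unusually *high* variability is flagged). Columns with fewer than
    ``min_values`` observed SEs are left unflagged.
    """
    flags = pd.DataFrame(False, index=se_table.index, columns=se_table.columns)
    for col in se_table.columns:
        vals = se_table[col].dropna()
        if len(vals) < min_values:
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        thresh = q3 + g * (q3 - q1)
        flags[col] = se_table[col] > thresh
    return flags


def apply_se_screen(table: LITable, se_table: pd.DataFrame, g: float = HOAGLIN_IGLEWICZ_G) -> LITable:
    """Blank LI cells flagged by :func:`se_outlier_screen` (reason high-SE)."""
    out = table.copy()
    flags = se_outlier_screen(se_table.reindex(index=out.data.index), g=g)
    for subj in out.data.index:
        for ind in INDICATORS:
            if bool(flags.loc[subj, ind]) and pd.notna(out.data.loc[subj, ind]):
                out.data.loc[subj, ind] = np.nan
                out.reasons[(subj, ind)] = "high-SE"
    return out


def apply_exclusion_rules(table: LITable, min_trials: int = MIN_TRIALS) -> tuple[LITable, dict]:
    """Apply the trial-count and whole-participant exclusion rules.

    Cells with fewer than ``min_trials`` usable trials become missing
    (reason low-trial-count). A task counts as excluded for a participant
    when either session's cell is missing *for quality reasons* (high-SE,
    low-trial-count or no-usable-trials — not structural missingness);
    participants with more than one excluded task are dropped entirely.
    Idempotent. Returns the cleaned table and an exclusion report.
    """
    quality = {"high-SE", "low-trial-count", "no-usable-trials"}
    out = table.copy()
    report = {"cells_removed": [], "participants_removed": []}
    if out.counts is not None:
        for subj in out.data.index:
            for ind in INDICATORS:
                if pd.notna(out.data.loc[subj, ind]) and out.counts.loc[subj, ind] < min_trials:
                    out.data.loc[subj, ind] = np.nan
                    out.reasons[(subj, ind)] = "low-trial-count"
                    report["cells_removed"].append(
                        {"subject": subj, "indicator": ind, "reason": "low-trial-count"}
                    )
    drop = []
    for subj in out.data.index:
        bad_tasks = set()
        for t in TASKS:
            for s in (1, 2):
                if out.reasons.get((subj, f"{t}{s}")) in quality:
                    bad_tasks.add(t)
        if len(bad_tasks) > 1:
            drop.append(subj)
            report["participants_removed"].append(
                {"subject": subj, "excluded_tasks": sorted(bad_tasks)}
            )
    if drop:
        out.data = out.data.drop(index=drop)
        if out.counts is not None:
            out.counts = out.counts.drop(index=drop)
        out.reasons = {k: v for k, v in out.reasons.items() if k[0] not in set(drop)}
    return out, report


def extract_li_table(
    epoch_sets: dict,
    meta: pd.DataFrame,
    poi: tuple[float, float] = DEFAULT_POI,
    min_trials: int = MIN_TRIALS,
    se_screen: bool = True,
) -> tuple[LITable, dict]:
    """Full LI + QC stage from preprocessed epochs.

    ``epoch_sets`` maps ``(subject, indicator)`` (e.g. ``("S001", "D1")``)
    to a preprocessed :class:`EpochSet`. Computes LIs, applies the high-SE
    screen and the exclusion rules, and returns the table plus report.
    """
    estimates, ses = {}, {}
    for (subj, ind), ep in epoch_sets.items():
        est = compute_li(ep, poi=poi)
        estimates[(subj, ind)] = est
        ses[(subj, ind)] = est.se
    table = build_li_table(estimates, meta)
    if se_screen:
        se_df = pd.DataFrame(
            {ind: {s: ses.get((s, ind), np.nan) for s in meta.index} for ind in INDICATORS}
        )
        table = apply_se_screen(table, se_df)
    return apply_exclusion_rules(table, min_trials=min_trials)
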