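"""Non-refined factor scores (weighted LI means), outlier flagging and
group dispersion.

A participant's score on each factor is the loading-weighted *mean* of
their session-averaged task LIs (weights renormalized over the tasks that
participant actually has), so scores stay on the original LI scale.
Outliers are flagged per group at more than ``multiplier`` times the mean
Cook's distance, either from the regression of the factor-2 score on the
factor-1 score (default) or from Mahalanobis leverage of the bivariate
cloud.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cfa import FitResult
from .types import TASKS, LITable


def weighted_li_means(fit_result, table: LITable) -> pd.DataFrame:
    """Per-participant weighted LI means for each factor.

    ``fit_result`` is a :class:`~ftcdlat.cfa.FitResult` (loadings taken per
    group, falling back to the single-group loadings when the fit is not
    multigroup) or a mapping group -> task x factor loading DataFrame.
    Sessions are averaged per task ignoring missing cells; tasks missing
    both sessions drop out of both numerator and denominator. A factor
    whose included-task loadings sum to ~0 yields an undefined (NaN) score
    with an ``undefined`` flag.
    """
    if isinstance(fit_result, FitResult):
        groups = fit_result.spec.groups
        loadings = {g: fit_result.loadings(g) for g in groups}
    else:
        loadings = {g: pd.DataFrame(v) for g, v in dict(fit_result).items()}
    means = table.session_means()
    rows = []
    for subj in table.data.index:
        group = table.data.loc[subj, "group"]
        lam = loadings.get(group)
        if lam is None:
            lam = next(iter(loadings.values()))
        row = {"subject": subj, "group": group}
        li = means.loc[subj]
        present = [t for t in TASKS if pd.notna(li[t])]
        for fcol in lam.columns:
            w = lam.loc[present, fcol].to_numpy(float)
            denom = w.sum()
            if len(present) == 0 or abs(denom) < 1e-12:
                row[fcol] = np.nan
                row[f"{fcol}_undefined"] = True
            else:
                row[fcol] = float(np.dot(w, li[present].to_numpy(float)) / denom)
                row[f"{fcol}_undefined"] = False
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def cooks_outliers(
    scores: pd.DataFrame,
    multiplier: float = 4.0,
    method: str = "regression",
    x: str = "factor1",
    y: str = "factor2",
) -> pd.Series:
    """Flag participants whose influence exceeds ``multiplier`` times the
    group mean.

    ``method='regression'`` uses Cook's distance from the per-group OLS of
    the factor-2 score on the factor-1 score; ``method='mahalanobis'`` uses
    squared Mahalanobis distance of the bivariate score instead. Groups
    need at least 5 complete score pairs; degenerate (constant) scores
    yield no flags with a warning.
    """
    flags = pd.Series(False, index=scores.index)
    for group, sub in scores.groupby("group"):
        sub = sub[[x, y]].dropna()
        if len(sub) < 5:
            raise ValueError(f"group {group!r} has fewer than 5 complete score pairs")
        xv = sub[x].to_numpy(float)
        yv = sub[y].to_numpy(float)
        if np.std(xv) < 1e-12 or np.std(yv) < 1e-12:
            warnings.warn(f"group {group!r}: degenerate (constant) scores; no outlier flags")
            continue
        if method == "regression":
            model = sm.OLS(yv, sm.add_constant(xv)).fit()
            dist = model.get_influence().cooks_distance[0]
        elif method == "mahalanobis":
            pts = sub.to_numpy(float)
            center = pts.mean(axis=0)
            cov = np.cov(pts.T)
            inv = np.linalg.pinv(cov)
            d = pts - center
            dist = np.einsum("ij,jk,ik->i", d, inv, d)
        else:
            raise ValueError("method must be 'regression' or 'mahalanobis'")
        mean_d = dist.mean()
        if mean_d <= 0 or not np.isfinite(mean_d):
            continue
        flags.loc[sub.index] = dist > multiplier * mean_d
    return flags


def covariance_ellipse(points: np.ndarray, coverage: float = 0.95) -> dict:
    """95% covariance ellipse of a bivariate cloud.

    Returns center, semi-axis lengths (sqrt of chi2 quantile times the
    covariance eigenvalues) and orientation in radians.
    """
    pts = np.asarray(points, float)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = sps.chi2.ppf(coverage, df=2)
    return {
        "center": center,
        "cov": cov,
        "semi_axes": np.sqrt(np.maximum(evals, 0.0) * q),
        "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        "coverage": coverage,
    }


def ellipse_contains(ellipse: dict, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside the covariance ellipse."""
    pts = np.asarray(points, float)
    d = pts - ellipse["center"]
    inv = np.linalg.pinv(ellipse["cov"])
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    return md2 <= sps.chi2.ppf(ellipse["coverage"], df=2)


def group_dispersion(
    scores: pd.DataFrame, x: str = "factor1", y: str = "factor2"
) -> dict:
    """Per-group Pearson correlation between the two factor scores and the
    95% covariance ellipse of the bivariate cloud."""
    out = {}
    for group, sub in scores.groupby("group"):
        sub = sub[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 complete score pairs")
        pts = sub.to_numpy(float)
        if np.std(pts[:, 0]) < 1e-12 or np.std(pts[:, 1]) < 1e-12:
            r = np.nan
        else:
            r = float(sps.pearsonr(pts[:, 0], pts[:, 1])[0])
        out[group] = {"n": len(sub), "r": r, "ellipse": covariance_ellipse(pts)}
    return out
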