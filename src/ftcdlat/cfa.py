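"""Confirmatory factor analysis of laterality covariance with
full-information maximum likelihood (FIML).

Model family
------------
Twelve indicators (tasks A-F at sessions 1 and 2) load on one or two
orthogonal latent laterality factors. Identification follows the marker
convention: the Sentence Generation task (D) has its loading fixed at 1 on
factor 1 and 0 on factor 2; factor means are fixed at 0; factor 1's
variance is free and factor 2's is fixed at 1; the factor covariance is
fixed at 0. Loadings, task means and residual variances are tied across
sessions (6 free means, 6 free residual variances). Multigroup variants fit
left- and right-handers simultaneously with either shared ("constrained")
or group-specific ("unconstrained") loadings. Free-parameter counts:
18 (single group, 1 factor), 23 (single group, 2 factors), 36 (multigroup
constrained), 46 (multigroup unconstrained).

Estimation
----------
Raw data enter directly: each participant contributes the marginal
multivariate-normal deviance of their observed cells under the group's
model-implied mean and covariance (FIML; no imputation). Rows are grouped
by missingness pattern and summarized by per-pattern sufficient statistics,
so a deviance evaluation costs one Cholesky factorization per pattern. The
deviance is minimized by bounded quasi-Newton (L-BFGS-B) on a transformed
parameterization (log residual and factor variances) with jittered,
moment-based multi-starts. Degrees of freedom follow the raw-data
convention: observed data points minus free parameters. AIC/BIC use the Mx
conventions AIC = deviance - 2*df and BIC = deviance - df*ln(N).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .types import INDICATORS, MARKER_TASK, TASKS, LITable

LOG2PI = float(np.log(2.0 * np.pi))
FREE_TASKS = [t for t in TASKS if t != MARKER_TASK]  # A, B, C, E, F
_PENALTY = 1e12


# ======================================================================
# Model specification
# ======================================================================
@dataclass(frozen=True)
class CFAModelSpec:
    """Constraint pattern for one model variant (see module docstring)."""

    n_factors: int
    groups: tuple[str, ...] = ("all",)
    shared_loadings: bool = True

    def __post_init__(self):
        if self.n_factors not in (1, 2):
            raise ValueError("n_factors must be 1 or 2")
        if len(self.groups) > 1 and self.n_factors == 1:
            raise ValueError("multigroup one-factor models are not supported")
        if len(self.groups) == 1 and not self.shared_loadings:
            raise ValueError("unconstrained loadings require more than one group")

    @property
    def multigroup(self) -> bool:
        return len(self.groups) > 1

    def loading_names(self) -> list[str]:
        names = []
        blocks = [""] if self.shared_loadings else [f"@{g}" for g in self.groups]
        for suffix in blocks:
            names += [f"l1_{t}{suffix}" for t in FREE_TASKS]
            if self.n_factors == 2:
                names += [f"l2_{t}{suffix}" for t in FREE_TASKS]
        return names

    def group_param_names(self, g: str) -> list[str]:
        return (
            [f"psi1@{g}"]
            + [f"mu_{t}@{g}" for t in TASKS]
            + [f"theta_{t}@{g}" for t in TASKS]
        )

    def param_names(self) -> list[str]:
        names = self.loading_names()
        for g in self.groups:
            names += self.group_param_names(g)
        return names

    def count_free_parameters(self) -> int:
        return len(self.param_names())

    def log_scale_mask(self) -> np.ndarray:
        """True where the optimizer works on log scale (variances)."""
        return np.array(
            [n.startswith(("psi1", "theta")) for n in self.param_names()], dtype=bool
        )

    # ------------------------------------------------------------------
    def implied_moments(self, params: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-group model-implied (mean 12-vector, covariance 12x12)."""
        d = dict(zip(self.param_names(), np.asarray(params, float)))
        out = {}
        for g in self.groups:
            suffix = "" if self.shared_loadings else f"@{g}"
            lam = np.zeros((12, self.n_factors))
            for i, t in enumerate(TASKS):
                if t == MARKER_TASK:
                    lam[i, 0] = lam[i + 6, 0] = 1.0
                    # factor-2 marker loading fixed at 0
                else:
                    lam[i, 0] = lam[i + 6, 0] = d[f"l1_{t}{suffix}"]
                    if self.n_factors == 2:
                        lam[i, 1] = lam[i + 6, 1] = d[f"l2_{t}{suffix}"]
            phi = np.diag([d[f"psi1@{g}"]] + ([1.0] if self.n_factors == 2 else []))
            theta = np.array([d[f"theta_{t}@{g}"] for t in TASKS])
            mu = np.tile(np.array([d[f"mu_{t}@{g}"] for t in TASKS]), 2)
            sigma = lam @ phi @ lam.T + np.diag(np.tile(theta, 2))
            out[g] = (mu, sigma)
        return out

    def to_yaml_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "groups": list(self.groups),
            "shared_loadings": self.shared_loadings,
            "fixed": {
                "marker_task": MARKER_TASK,
                "marker_loadings": [1.0, 0.0],
                "factor_means": 0.0,
                "factor2_variance": 1.0,
                "factor_covariance": 0.0,
                "session_equality": ["loadings", "means", "residual_variances"],
            },
            "n_free_parameters": self.count_free_parameters(),
        }


def build_spec(
    factors: int, groups: str | Sequence[str] = "single", shared_loadings: bool = True
) -> CFAModelSpec:
    """Build the exact constraint pattern for one of the four model variants.

    ``groups`` is ``"single"`` (one group) or a sequence of group labels for
    a multigroup model. Multigroup one-factor models are rejected.
    """
    if isinstance(groups, str):
        gtuple = ("all",) if groups in ("single", "all") else (groups,)
    else:
        gtuple = tuple(groups)
    if len(gtuple) == 1:
        shared_loadings = True
    return CFAModelSpec(n_factors=factors, groups=gtuple, shared_loadings=shared_loadings)


# ======================================================================
# Data handling: missingness-pattern sufficient statistics
# ======================================================================
class _GroupData:
    """Rows of one group summarized per missingness pattern."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 12:
            raise ValueError("expected an (n, 12) indicator matrix")
        obs = np.isfinite(X)
        if np.any(obs.sum(axis=1) == 0):
            raise ValueError("every row must have at least one observed cell")
        self.n_rows = X.shape[0]
        self.n_cells = int(obs.sum())
        self.patterns = []
        keys = [tuple(row) for row in obs]
        for key in sorted(set(keys)):
            sel = np.array([k == key for k in keys])
            idx = np.nonzero(np.array(key))[0]
            sub = X[np.ix_(sel, idx)]
            m = sub.shape[0]
            xbar = sub.mean(axis=0)
            centered = sub - xbar
            scatter = centered.T @ centered / m
            self.patterns.append({"idx": idx, "n": m, "xbar": xbar, "S": scatter})

    def deviance(self, mu: np.ndarray, sigma: np.ndarray) -> Optional[float]:
        """-2 log-likelihood; None if any observed submatrix is not PD."""
        total = 0.0
        for pat in self.patterns:
            o = pat["idx"]
            sub = sigma[np.ix_(o, o)]
            try:
                c, low = cho_factor(sub, lower=True)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.diag(c) > 0):
                return None
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            diff = pat["xbar"] - mu[o]
            tr = float(np.trace(cho_solve((c, low), pat["S"])))
            mahal = float(diff @ cho_solve((c, low), diff))
            total += pat["n"] * (len(o) * LOG2PI + logdet + tr + mahal)
        return total


def _coerce_groups(table, spec: CFAModelSpec, groups=None) -> dict[str, np.ndarray]:
    """Map spec group labels to (n, 12) indicator matrices."""
    if isinstance(table, LITable):
        frame = table.values
        labels = table.groups
    elif isinstance(table, pd.DataFrame):
        frame = table.loc[:, INDICATORS]
        labels = pd.Series(groups, index=frame.index) if groups is not None else None
    else:
        frame = pd.DataFrame(np.asarray(table, float), columns=INDICATORS)
        labels = pd.Series(groups, index=frame.index) if groups is not None else None
    if spec.multigroup:
        if labels is None:
            raise ValueError("multigroup model requires group labels")
        out = {}
        for g in spec.groups:
            sub = frame[labels == g]
            if len(sub) == 0:
                raise ValueError(f"group {g!r} has no rows")
            out[g] = sub.to_numpy(float)
        return out
    return {spec.groups[0]: frame.to_numpy(float)}


# ======================================================================
# Deviance and fitting
# ======================================================================
@lru_cache(maxsize=64)
def _index_maps(spec: CFAModelSpec):
    """Parameter-vector index maps per group (loadings, psi, means, thetas)."""
    names = spec.param_names()
    pos = {n: i for i, n in enumerate(names)}
    maps = {}
    for g in spec.groups:
        suffix = "" if spec.shared_loadings else f"@{g}"
        l1 = [(pos[f"l1_{t}{suffix}"], TASKS.index(t)) for t in FREE_TASKS]
        l2 = (
            [(pos[f"l2_{t}{suffix}"], TASKS.index(t)) for t in FREE_TASKS]
            if spec.n_factors == 2
            else []
        )
        maps[g] = {
            "l1": l1,
            "l2": l2,
            "psi": pos[f"psi1@{g}"],
            "mu": [pos[f"mu_{t}@{g}"] for t in TASKS],
            "theta": [pos[f"theta_{t}@{g}"] for t in TASKS],
        }
    return maps


def _build_group(spec: CFAModelSpec, params: np.ndarray, g: str):
    """(mu12, Sigma, Lambda, phi_diag) for one group from the raw vector."""
    m = _index_maps(spec)[g]
    lam = np.zeros((12, spec.n_factors))
    lam[TASKS.index(MARKER_TASK), 0] = lam[TASKS.index(MARKER_TASK) + 6, 0] = 1.0
    for pi, t in m["l1"]:
        lam[t, 0] = lam[t + 6, 0] = params[pi]
    for pi, t in m["l2"]:
        lam[t, 1] = lam[t + 6, 1] = params[pi]
    phi = np.array([params[m["psi"]]] + ([1.0] if spec.n_factors == 2 else []))
    theta6 = params[m["theta"]]
    mu = np.tile(params[m["mu"]], 2)
    sigma = (lam * phi) @ lam.T + np.diag(np.tile(theta6, 2))
    return mu, sigma, lam, phi


def _deviance_and_grad(
    spec: CFAModelSpec, params: np.ndarray, data: dict[str, "_GroupData"]
) -> tuple[float, np.ndarray]:
    """FIML deviance and its analytic gradient in raw parameter space.

    Per pattern the deviance gradient w.r.t. the implied moments is
    dD/dSigma_oo = n (S^-1 - S^-1 (Scatter + dd') S^-1) and
    dD/dmu_o = -2 n S^-1 d; the chain rule maps these onto loadings
    (dSigma = dLam Phi Lam' + ..., summed over the two tied session rows),
    the factor-1 variance, and the session-tied residual variances/means.
    """
    grad = np.zeros_like(params)
    total = 0.0
    maps = _index_maps(spec)
    for g, gd in data.items():
        mu, sigma, lam, phi = _build_group(spec, params, g)
        G = np.zeros((12, 12))
        gmu = np.zeros(12)
        for pat in gd.patterns:
            o = pat["idx"]
            sub = sigma[np.ix_(o, o)]
            try:
                c, low = cho_factor(sub, lower=True)
            except np.linalg.LinAlgError:
                pen = _PENALTY * (1.0 + 1e-6 * float(np.sum(params**2)))
                return pen, 2e-6 * _PENALTY * params
            if not np.all(np.diag(c) > 0):
                pen = _PENALTY * (1.0 + 1e-6 * float(np.sum(params**2)))
                return pen, 2e-6 * _PENALTY * params
            n = pat["n"]
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            d = pat["xbar"] - mu[o]
            sinv = cho_solve((c, low), np.eye(len(o)))
            sinv_d = sinv @ d
            total += n * (
                len(o) * LOG2PI
                + logdet
                + float(np.sum(sinv * pat["S"]))
                + float(d @ sinv_d)
            )
            A = sinv @ (pat["S"] + np.outer(d, d)) @ sinv
            G[np.ix_(o, o)] += n * (sinv - A)
            gmu[o] += -2.0 * n * sinv_d
        m = maps[g]
        lam_phi = lam * phi  # columns scaled by factor variances
        M = G @ lam_phi
        for pi, t in m["l1"]:
            grad[pi] += 2.0 * (M[t, 0] + M[t + 6, 0])
        for pi, t in m["l2"]:
            grad[pi] += 2.0 * (M[t, 1] + M[t + 6, 1])
        grad[m["psi"]] += float(lam[:, 0] @ G @ lam[:, 0])
        dG = np.diag(G)
        gmu_t = gmu
        for i, t_idx in enumerate(range(6)):
            grad[m["theta"][i]] += dG[t_idx] + dG[t_idx + 6]
            grad[m["mu"][i]] += gmu_t[t_idx] + gmu_t[t_idx + 6]
    return total, grad


def fiml_deviance(spec: CFAModelSpec, params, table, groups=None) -> float:
    """FIML -2 log-likelihood of ``table`` at ``params``.

    ``params`` is a vector in ``spec.param_names()`` order or a name->value
    mapping. A singular implied covariance yields a large penalized value
    (with the constraint violation noted), never an exception.
    """
    if isinstance(params, dict):
        params = np.array([params[n] for n in spec.param_names()], float)
    data = {g: _GroupData(X) for g, X in _coerce_groups(table, spec, groups).items()}
    return _deviance(spec, np.asarray(params, float), data)


def _deviance(spec: CFAModelSpec, params: np.ndarray, data: dict[str, "_GroupData"]) -> float:
    implied = spec.implied_moments(params)
    total = 0.0
    for g, gd in data.items():
        dev = gd.deviance(*implied[g])
        if dev is None:
            return _PENALTY * (1.0 + 1e-6 * float(np.sum(params**2)))
        total += dev
    return total


@dataclass
class FitResult:
    """Converged model fit: estimates, deviance, df and diagnostics."""

    spec: Optional[CFAModelSpec]
    params: np.ndarray
    param_names: list[str]
    deviance: float
    n_free: int
    n_obs_cells: int
    n_rows: dict[str, int]
    converged: bool
    implied: dict[str, tuple[np.ndarray, np.ndarray]]
    se: Optional[dict[str, float]] = None
    message: str = ""
    kind: str = "model"  # 'model' | 'saturated' | 'independence'
    n_starts_converged: int = 0

    @property
    def df(self) -> int:
        return self.n_obs_cells - self.n_free

    @property
    def n_total(self) -> int:
        return int(sum(self.n_rows.values()))

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.params))

    def loadings(self, group: Optional[str] = None) -> pd.DataFrame:
        """Task x factor loading matrix (fixed marker row included)."""
        if self.spec is None:
            raise ValueError("no structural spec attached to this fit")
        spec = self.spec
        g = group if group is not None else spec.groups[0]
        suffix = "" if spec.shared_loadings else f"@{g}"
        d = self.param_dict
        cols = {}
        for f in range(1, spec.n_factors + 1):
            col = []
            for t in TASKS:
                if t == MARKER_TASK:
                    col.append(1.0 if f == 1 else 0.0)
                else:
                    col.append(d[f"l{f}_{t}{suffix}"])
            cols[f"factor{f}"] = col
        return pd.DataFrame(cols, index=TASKS)

    def loading_table(self, group: Optional[str] = None) -> pd.DataFrame:
        """Free loadings with Wald SEs and 95% CIs (marker rows omitted)."""
        if self.se is None:
            raise ValueError("standard errors were not computed for this fit")
        spec = self.spec
        g = group if group is not None else spec.groups[0]
        suffix = "" if spec.shared_loadings else f"@{g}"
        rows = []
        z = sps.norm.ppf(0.975)
        for f in range(1, spec.n_factors + 1):
            for t in FREE_TASKS:
                name = f"l{f}_{t}{suffix}"
                est = self.param_dict[name]
                se = self.se.get(name, np.nan)
                rows.append({
                    "task": t, "factor": f, "estimate": est, "se": se,
                    "ci_low": est - z * se, "ci_high": est + z * se,
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "deviance": float(self.deviance),
            "df": int(self.df),
            "n_free": int(self.n_free),
            "n_obs_cells": int(self.n_obs_cells),
            "n_rows": {k: int(v) for k, v in self.n_rows.items()},
            "converged": bool(self.converged),
            "estimates": {k: float(v) for k, v in self.param_dict.items()},
            "kind": self.kind,
        }
        if self.se is not None:
            out["se"] = {k: float(v) for k, v in self.se.items()}
        if self.spec is not None:
            out["model"] = self.spec.to_yaml_dict()
        return out


def _moment_starts(spec: CFAModelSpec, data: dict[str, np.ndarray]) -> np.ndarray:
    """Moment-based starting values (raw scale)."""
    names = spec.param_names()
    vals = dict.fromkeys(names, 0.0)
    lam_by_group = {}
    for g, X in data.items():
        df = pd.DataFrame(X, columns=INDICATORS)
        cov = df.cov(min_periods=2)
        mu6, var6 = [], []
        for t in TASKS:
            mu6.append(np.nanmean(df[[f"{t}1", f"{t}2"]].to_numpy()))
            var6.append(np.nanmean([df[f"{t}1"].var(), df[f"{t}2"].var()]))
        var6 = np.maximum(np.nan_to_num(np.array(var6), nan=1.0), 1e-3)
        psi0 = cov.loc[f"{MARKER_TASK}1", f"{MARKER_TASK}2"]
        if not np.isfinite(psi0) or psi0 < 0.1 * var6[TASKS.index(MARKER_TASK)]:
            psi0 = 0.5 * var6[TASKS.index(MARKER_TASK)]
        lam1 = {}
        for t in FREE_TASKS:
            cs = [cov.loc[f"{t}{a}", f"{MARKER_TASK}{b}"] for a in (1, 2) for b in (1, 2)]
            c = np.nanmean(cs)
            lam1[t] = float(np.clip(c / psi0, -2.0, 2.0)) if np.isfinite(c) else 0.5
        theta0 = {}
        for i, t in enumerate(TASKS):
            lam_t = 1.0 if t == MARKER_TASK else lam1[t]
            theta0[t] = float(np.clip(var6[i] - lam_t**2 * psi0, 0.1 * var6[i], None))
        vals[f"psi1@{g}"] = float(psi0)
        for i, t in enumerate(TASKS):
            vals[f"mu_{t}@{g}"] = float(np.nan_to_num(mu6[i], nan=0.0))
            vals[f"theta_{t}@{g}"] = theta0[t]
        lam_by_group[g] = lam1
    for name in spec.loading_names():
        kind, rest = name.split("_", 1)
        if "@" in rest:
            t, g = rest.split("@")
            vals[name] = lam_by_group[g][t] if kind == "l1" else 0.1
        else:
            t = rest
            if kind == "l1":
                vals[name] = float(np.mean([lam_by_group[g][t] for g in spec.groups]))
            else:
                vals[name] = 0.1
    return np.array([vals[n] for n in names], float)


def _to_z(spec: CFAModelSpec, params: np.ndarray) -> np.ndarray:
    z = np.array(params, float)
    mask = spec.log_scale_mask()
    z[mask] = np.log(np.maximum(z[mask], 1e-8))
    return z


def _from_z(spec: CFAModelSpec, z: np.ndarray) -> np.ndarray:
    x = np.array(z, float)
    mask = spec.log_scale_mask()
    x[mask] = np.exp(x[mask])
    return x


def fit(
    spec: CFAModelSpec,
    table,
    groups=None,
    starts: int = 5,
    seed: Optional[int] = 0,
    compute_se: bool = True,
    extra_starts: Optional[list[np.ndarray]] = None,
    maxiter: int = 2000,
) -> FitResult:
    """Fit ``spec`` to raw LI data by FIML.

    Minimizes the deviance with L-BFGS-B on the transformed parameter
    vector, from a moment-based start plus ``starts - 1`` jittered restarts
    (seed-controlled, so refitting the same table with the same seed gives
    identical estimates). ``extra_starts`` may supply additional raw-scale
    start vectors (used to warm-start a larger model from a nested fit).
    Raises if no start converges.
    """
    gdata = _coerce_groups(table, spec, groups)
    data = {g: _GroupData(X) for g, X in gdata.items()}
    n_obs_cells = sum(gd.n_cells for gd in data.values())
    n_free = spec.count_free_parameters()
    if n_obs_cells <= n_free:
        raise ValueError(
            f"not enough observed cells ({n_obs_cells}) for {n_free} free parameters"
        )
    rng = np.random.default_rng(seed)
    x0 = _moment_starts(spec, gdata)
    z0 = _to_z(spec, x0)
    mask = spec.log_scale_mask()
    lower = np.where(mask, np.log(1e-8), -1e4)
    upper = np.where(mask, np.log(1e8), 1e4)
    names = spec.param_names()
    lower[[n.startswith("l") for n in names]] = -50.0
    upper[[n.startswith("l") for n in names]] = 50.0
    bounds = list(zip(lower, upper))

    def objective(z: np.ndarray):
        x = _from_z(spec, z)
        f, g = _deviance_and_grad(spec, x, data)
        gz = g.copy()
        gz[mask] = gz[mask] * x[mask]  # chain rule through the log transform
        return f, gz

    start_list = [z0]
    for _ in range(max(0, starts - 1)):
        start_list.append(z0 + rng.normal(0.0, 0.2, size=len(z0)))
    for xs in extra_starts or []:
        start_list.append(_to_z(spec, np.asarray(xs, float)))

    best, n_ok = None, 0
    for z_init in start_list:
        res = optimize.minimize(
            objective,
            np.clip(z_init, lower + 1e-9, upper - 1e-9),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        if res.fun < _PENALTY / 2:
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-10:
                best = res
    if best is None:
        raise RuntimeError("no optimization start converged to a proper solution")
    params = _from_z(spec, best.x)
    se = _wald_se(spec, params, data, names) if compute_se else None
    return FitResult(
        spec=spec,
        params=params,
        param_names=names,
        deviance=float(best.fun),
        n_free=n_free,
        n_obs_cells=n_obs_cells,
        n_rows={g: gd.n_rows for g, gd in data.items()},
        converged=bool(best.success or np.max(np.abs(best.jac)) < 1e-3),
        implied=spec.implied_moments(params),
        se=se,
        message=str(best.message),
        n_starts_converged=n_ok,
    )


def _wald_se(spec, params, data, names) -> dict[str, float]:
    """SEs from the numerical Hessian of the deviance at the optimum.

    The Hessian is built by central differences of the analytic gradient;
    Cov(theta) = 2 * H^{-1} since the deviance is twice the negative
    log-likelihood.
    """
    k = len(params)
    h = 1e-5 * np.maximum(1.0, np.abs(params))
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        _, gp = _deviance_and_grad(spec, params + e, data)
        _, gm = _deviance_and_grad(spec, params - e, data)
        H[:, i] = (gp - gm) / (2 * h[i])
    H = (H + H.T) / 2
    try:
        cov = 2.0 * np.linalg.pinv(H)
        diag = np.diag(cov)
        return {n: (float(np.sqrt(d)) if d > 0 else np.nan) for n, d in zip(names, diag)}
    except np.linalg.LinAlgError:  # pragma: no cover
        return {n: np.nan for n in names}


# ======================================================================
# Saturated and independence (baseline) models
# ======================================================================
def _em_mvn(X: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """ML mean/covariance of an incomplete MVN sample via EM."""
    n, p = X.shape
    obs = np.isfinite(X)
    mu = np.array([np.nanmean(X[:, j]) if obs[:, j].any() else 0.0 for j in range(p)])
    var = np.array([np.nanvar(X[:, j]) if obs[:, j].sum() > 1 else 1.0 for j in range(p)])
    sigma = np.diag(np.maximum(var, 1e-6))
    gd = _GroupData(X)
    if all(len(pat["idx"]) == p for pat in gd.patterns):  # complete data: closed form
        mu = X.mean(axis=0)
        xc = X - mu
        return mu, xc.T @ xc / n
    prev = None
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for i in range(n):
            o = np.nonzero(obs[i])[0]
            m = np.nonzero(~obs[i])[0]
            x = np.zeros(p)
            x[o] = X[i, o]
            cxx = np.zeros((p, p))
            if len(m):
                soo = sigma[np.ix_(o, o)]
                som = sigma[np.ix_(o, m)]
                smm = sigma[np.ix_(m, m)]
                c, low = cho_factor(soo + 1e-12 * np.eye(len(o)), lower=True)
                x[m] = mu[m] + som.T @ cho_solve((c, low), X[i, o] - mu[o])
                cxx[np.ix_(m, m)] = smm - som.T @ cho_solve((c, low), som)
            sum_x += x
            sum_xx += np.outer(x, x) + cxx
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2 + 1e-12 * np.eye(p)
        dev = gd.deviance(mu, sigma)
        if dev is not None and prev is not None and abs(prev - dev) < tol * max(1.0, abs(dev)):
            break
        prev = dev
    return mu, sigma


def fit_saturated(table, groups=None, group_labels: Optional[Sequence[str]] = None) -> FitResult:
    """Saturated model: free per-group mean vector and full covariance.

    Deviance is the FIML deviance at the EM maximum-likelihood moments
    (closed form for complete data); 90 free parameters per group.
    """
    labels, gdata = _resolve_groups(table, groups, group_labels)
    implied, n_rows, n_cells, dev = {}, {}, 0, 0.0
    for g in labels:
        X = gdata[g]
        gd = _GroupData(X)
        mu, sigma = _em_mvn(X)
        d = gd.deviance(mu, sigma)
        if d is None:
            raise RuntimeError("saturated covariance is singular")
        implied[g] = (mu, sigma)
        n_rows[g] = gd.n_rows
        n_cells += gd.n_cells
        dev += d
    n_free = 90 * len(labels)
    return FitResult(
        spec=None, params=np.array([]), param_names=[], deviance=dev, n_free=n_free,
        n_obs_cells=n_cells, n_rows=n_rows, converged=True, implied=implied,
        kind="saturated",
    )


def fit_independence(table, groups=None, group_labels: Optional[Sequence[str]] = None) -> FitResult:
    """Baseline model: free mean and variance per indicator, zero
    covariances, no equality constraints (24 parameters per group)."""
    labels, gdata = _resolve_groups(table, groups, group_labels)
    implied, n_rows, n_cells, dev = {}, {}, 0, 0.0
    for g in labels:
        X = gdata[g]
        mu = np.zeros(12)
        var = np.zeros(12)
        for j in range(12):
            col = X[:, j]
            col = col[np.isfinite(col)]
            mu[j] = col.mean()
            var[j] = max(col.var(), 1e-12)
            dev += len(col) * (LOG2PI + np.log(var[j]) + 1.0)
        implied[g] = (mu, np.diag(var))
        n_rows[g] = X.shape[0]
        n_cells += int(np.isfinite(X).sum())
    n_free = 24 * len(labels)
    return FitResult(
        spec=None, params=np.array([]), param_names=[], deviance=float(dev), n_free=n_free,
        n_obs_cells=n_cells, n_rows=n_rows, converged=True, implied=implied,
        kind="independence",
    )


def _resolve_groups(table, groups, group_labels):
    if isinstance(table, LITable) and group_labels is None:
        if groups == "by_group" or groups is True:
            labels = tuple(sorted(table.groups.unique()))
        else:
            labels = ("all",)
    else:
        labels = tuple(group_labels) if group_labels else ("all",)
    spec = CFAModelSpec(n_factors=2, groups=labels if len(labels) > 1 else ("all",),
                        shared_loadings=True) if len(labels) > 1 else None
    if len(labels) > 1:
        gdata = _coerce_groups(table, spec)
    else:
        if isinstance(table, LITable):
            gdata = {"all": table.values.to_numpy(float)}
        elif isinstance(table, pd.DataFrame):
            gdata = {"all": table.loc[:, INDICATORS].to_numpy(float)}
        else:
            gdata = {"all": np.asarray(table, float)}
    return labels, gdata


# ======================================================================
# Model comparison
# ======================================================================
def mx_aic(deviance: float, df: int) -> float:
    """Mx-convention AIC = deviance - 2*df."""
    return deviance - 2.0 * df


def mx_bic(deviance: float, df: int, n: int) -> float:
    """Mx-convention BIC = deviance - df*ln(N)."""
    return deviance - df * float(np.log(n))


def fit_indices(
    fit_result: FitResult,
    saturated: FitResult,
    independence: FitResult,
    n_obs: Optional[int] = None,
) -> dict:
    """Chi-square, CFI, RMSEA and Mx AIC/BIC for a fitted model.

    chi2 = model deviance minus saturated deviance; CFI uses the
    independence model as baseline; RMSEA = sqrt(max(chi2-df,0)/(df*N)).
    ``n_obs`` defaults to the total row count across groups.
    """
    for other in (saturated, independence):
        if other.n_obs_cells != fit_result.n_obs_cells:
            raise ValueError("all three fits must be computed on identical data")
    n = int(n_obs) if n_obs is not None else fit_result.n_total
    chi2_m = fit_result.deviance - saturated.deviance
    if chi2_m < -1e-6:
        raise ValueError(
            "saturated deviance exceeds model deviance; inconsistent fits"
        )
    chi2_m = max(chi2_m, 0.0)
    df_m = saturated.n_free - fit_result.n_free
    chi2_b = max(independence.deviance - saturated.deviance, 0.0)
    df_b = saturated.n_free - independence.n_free
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if den <= 0 else 1.0 - min(num / den, 1.0)
    rmsea = float(np.sqrt(num / (df_m * n))) if df_m > 0 else 0.0
    return {
        "chi2": float(chi2_m),
        "chi2_df": int(df_m),
        "chi2_p": float(sps.chi2.sf(chi2_m, df_m)) if df_m > 0 else np.nan,
        "cfi": float(cfi),
        "rmsea": rmsea,
        "aic": mx_aic(fit_result.deviance, fit_result.df),
        "bic": mx_bic(fit_result.deviance, fit_result.df, n),
        "n_obs": n,
    }


def lrt_from_deviances(dev_small: float, dev_large: float, df_diff: int) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, df and upper-tail chi-square p-value."""
    stat = dev_small - dev_large
    if stat < 0:
        stat = max(stat, 0.0) if stat > -1e-6 else stat
    if df_diff <= 0:
        raise ValueError("the larger model must have more free parameters")
    p = float(sps.chi2.sf(max(stat, 0.0), df_diff))
    return float(stat), int(df_diff), p


def _is_nested(small: CFAModelSpec, large: CFAModelSpec) -> bool:
    if small.groups != large.groups:
        return False
    if small.n_factors == 1 and large.n_factors == 2:
        return small.shared_loadings and large.shared_loadings
    if small.n_factors == large.n_factors == 2:
        return small.shared_loadings and not large.shared_loadings
    return False


def likelihood_ratio_test(fit_small: FitResult, fit_large: FitResult) -> dict:
    """LRT between two nested fits on identical data."""
    if fit_small.spec is not None and fit_large.spec is not None:
        if not _is_nested(fit_small.spec, fit_large.spec):
            raise ValueError("models are not nested")
    if fit_small.n_obs_cells != fit_large.n_obs_cells:
        raise ValueError("fits must be on identical data")
    stat, df, p = lrt_from_deviances(
        fit_small.deviance, fit_large.deviance, fit_large.n_free - fit_small.n_free
    )
    return {"statistic": stat, "df": df, "p": p}


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Normalized exp(-dAIC/2) weights (conditional model probabilities)."""
    a = np.asarray(aics, float)
    if len(a) < 2:
        raise ValueError("need at least two AIC values")
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def _embed_start(small: CFAModelSpec, params: np.ndarray, large: CFAModelSpec) -> np.ndarray:
    """Warm-start vector for the larger model from a nested solution."""
    d = dict(zip(small.param_names(), params))
    out = []
    for name in large.param_names():
        if name in d:
            out.append(d[name])
        elif "@" in name and name.split("@")[0] in d:  # shared -> group-specific
            out.append(d[name.split("@")[0]])
        elif name.startswith("l2_"):  # added factor loadings
            out.append(0.05)
        else:  # pragma: no cover
            out.append(0.1)
    return np.array(out, float)


def fit_nested_pair(
    table,
    spec_small: CFAModelSpec,
    spec_large: CFAModelSpec,
    groups=None,
    starts: int = 5,
    seed: Optional[int] = 0,
    compute_se: bool = False,
) -> tuple[FitResult, FitResult, dict]:
    """Fit a nested model pair and their LRT; the larger model gets an extra
    start embedded from the smaller solution, which guarantees the nested
    deviance ordering at the optimum."""
    if not _is_nested(spec_small, spec_large):
        raise ValueError("models are not nested")
    small = fit(spec_small, table, groups=groups, starts=starts, seed=seed, compute_se=compute_se)
    warm = _embed_start(spec_small, small.params, spec_large)
    large = fit(
        spec_large, table, groups=groups, starts=starts, seed=seed,
        compute_se=compute_se, extra_starts=[warm],
    )
    return small, large, likelihood_ratio_test(small, large)


def leave_one_out(
    table,
    spec_small: CFAModelSpec,
    spec_large: CFAModelSpec,
    groups=None,
    alpha: float = 0.05,
    starts: int = 2,
    seed: Optional[int] = 0,
) -> dict:
    """Leave-one-out stability of the nested model comparison.

    Refits both models with each row removed and records the LRT p-value.
    Iterations that fail to converge are recorded, not fatal. Returns the
    per-iteration results and the count significant at ``alpha``.
    """
    if isinstance(table, LITable):
        frame = table.data
        labels = frame["group"]
    else:
        frame = table if isinstance(table, pd.DataFrame) else pd.DataFrame(
            np.asarray(table, float), columns=INDICATORS
        )
        labels = pd.Series(groups, index=frame.index) if groups is not None else None
    if len(frame) < 10:
        raise ValueError("leave-one-out requires at least 10 rows")
    results = []
    for row in frame.index:
        sub = frame.drop(index=row)
        sub_groups = labels.drop(index=row) if labels is not None else None
        try:
            _, _, lrt = fit_nested_pair(
                sub[INDICATORS] if isinstance(sub, pd.DataFrame) else sub,
                spec_small, spec_large,
                groups=sub_groups, starts=starts, seed=seed, compute_se=False,
            )
            results.append({"left_out": row, "statistic": lrt["statistic"],
                            "df": lrt["df"], "p": lrt["p"], "converged": True})
        except (RuntimeError, ValueError) as exc:
            results.append({"left_out": row, "statistic": np.nan, "df": np.nan,
                            "p": np.nan, "converged": False, "error": str(exc)})
    n_sig = sum(1 for r in results if r["converged"] and r["p"] < alpha)
    return {
        "iterations": results,
        "n_iterations": len(results),
        "n_significant": n_sig,
        "alpha": alpha,
    }


# ======================================================================
# Estimator surface
# ======================================================================
class ConfirmatoryFactorModel(BaseEstimator):
    """Scikit-learn-style estimator for the laterality CFA.

    Parameters
    ----------
    n_factors : 1 or 2
    multigroup : fit left/right groups simultaneously
    shared_loadings : tie loadings across groups (multigroup only)
    n_starts, seed : multi-start optimization control
    compute_se : Wald standard errors from the numerical Hessian

    Fitted attributes (trailing underscore): ``result_``, ``loadings_``
    (dict group -> task x factor DataFrame), ``deviance_``, ``df_``,
    ``params_``, ``se_``, ``converged_``, ``spec_``.
    """

    def __init__(
        self,
        n_factors: int = 2,
        multigroup: bool = False,
        shared_loadings: bool = True,
        n_starts: int = 5,
        seed: Optional[int] = 0,
        compute_se: bool = True,
    ):
        self.n_factors = n_factors
        self.multigroup = multigroup
        self.shared_loadings = shared_loadings
        self.n_starts = n_starts
        self.seed = seed
        self.compute_se = compute_se

    def fit(self, X, y=None, groups=None):
        if self.multigroup:
            if isinstance(X, LITable):
                labels = tuple(sorted(X.groups.unique()))
            elif groups is not None:
                labels = tuple(sorted(pd.unique(np.asarray(groups))))
            else:
                raise ValueError("multigroup fit requires group labels")
            spec = build_spec(self.n_factors, groups=labels, shared_loadings=self.shared_loadings)
        else:
            spec = build_spec(self.n_factors, groups="single")
        result = fit(
            spec, X, groups=groups, starts=self.n_starts, seed=self.seed,
            compute_se=self.compute_se,
        )
        self.spec_ = spec
        self.result_ = result
        self.params_ = result.param_dict
        self.deviance_ = result.deviance
        self.df_ = result.df
        self.n_obs_cells_ = result.n_obs_cells
        self.se_ = result.se
        self.converged_ = result.converged
        self.loadings_ = {g: result.loadings(g) for g in spec.groups}
        self.n_features_in_ = 12
        return self

    def score(self, X, y=None, groups=None):
        """Mean log-likelihood per row at the fitted parameters."""
        dev = fiml_deviance(self.spec_, self.result_.params, X, groups=groups)
        gdata = _coerce_groups(X, self.spec_, groups)
        n = sum(v.shape[0] for v in gdata.values())
        return -0.5 * dev / n
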