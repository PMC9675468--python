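"""Patient-level metrics and the statistical layer.

Group comparisons use Welch's unequal-variance t-test with Holm
step-down adjustment within each comparison family; paired time-point
contrasts use a one-sample t-test on within-patient differences;
correlations use Spearman's rho with Benjamini-Hochberg FDR adjustment;
survival uses a Cox proportional-hazards model (Newton-Raphson on the
partial likelihood, Breslow tie handling), typically on a high/low
median split of a patient metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_CELLS = 50


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    n_a: int
    n_b: int
    test: str
    degenerate: bool = False


@dataclass
class SurvivalFit:
    coef: float
    hr: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    separation: bool
    stratifier: str = ""


def patient_means(cell_values: np.ndarray, cell_meta: pd.DataFrame,
                  by: tuple = ("patient_id", "timepoint"),
                  min_cells: int = DEFAULT_MIN_CELLS, name: str = "metric") -> pd.DataFrame:
    """Arithmetic mean of a per-cell metric per (patient, timepoint), with
    cell counts and a low-count flag."""
    by = [b for b in by if b in cell_meta.columns]
    if not by:
        raise ValueError("no grouping columns present in cell_meta")
    df = cell_meta[by].copy()
    if df.isna().any().any():
        raise ValueError("cells with missing grouping metadata")
    df[name] = np.asarray(cell_values, dtype=np.float64)
    out = df.groupby(by, sort=True)[name].agg(["mean", "count"]).reset_index()
    out = out.rename(columns={"mean": name, "count": "n_cells"})
    out["low_count"] = out["n_cells"] < min_cells
    if out["low_count"].any():
        warnings.warn(f"{int(out['low_count'].sum())} patient means below {min_cells} cells")
    return out


def unpaired_ttest(group_a, group_b) -> TTestResult:
    """Welch two-sided t-test, with a p=1 convention for identical
    zero-variance groups."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, len(a), len(b), "unpaired_t")
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf,
                           float(len(a) + len(b) - 2), 0.0, len(a), len(b), "unpaired_t", degenerate=True)
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), len(a), len(b), "unpaired_t")


def paired_ttest(before, after) -> TTestResult:
    """Paired two-sided t-test: one-sample t on within-patient differences."""
    x = np.asarray(before, dtype=np.float64)
    y = np.asarray(after, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("before/after must pair 1:1 by patient")
    if len(x) < 2:
        raise ValueError("need n >= 2 pairs")
    d = y - x
    if d.var(ddof=1) == 0:
        if d.mean() == 0:
            return TTestResult(0.0, float(len(d) - 1), 1.0, len(d), len(d), "paired_t")
        return TTestResult(np.inf if d.mean() > 0 else -np.inf, float(len(d) - 1), 0.0,
                           len(d), len(d), "paired_t", degenerate=True)
    t, p = sps.ttest_1samp(d, 0.0)
    return TTestResult(float(t), float(len(d) - 1), float(p), len(d), len(d), "paired_t")


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_fdr(pairs: list[tuple]) -> pd.DataFrame:
    """Spearman rho for each named (x, y) pair, BH-adjusted across the set.

    ``pairs`` is a list of (name, x, y).
    """
    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.shape != y.shape:
            raise ValueError(f"{name}: length mismatch")
        if len(x) < 3:
            raise ValueError(f"{name}: need n >= 3")
        rho, p = sps.spearmanr(x, y)
        rows.append({"pair": name, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def median_split(values) -> np.ndarray:
    """High/low labels at the median; ties at the median go to 'low'."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need >= 2 patients to split")
    med = np.median(v)
    labels = np.where(v > med, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("no split possible (all values at or below the median)")
    return labels


def _cox_loglik_parts(beta: float, time, event, x):
    """Breslow partial log-likelihood with gradient and negative Hessian."""
    order = np.argsort(time, kind="stable")
    t, e, xv = np.asarray(time)[order], np.asarray(event)[order], np.asarray(x, dtype=np.float64)[order]
    eta = beta * xv
    w = np.exp(eta)
    # suffix sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]
    ll = grad = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k]]
        d = len(d_idx)
        if d:
            xs = xv[d_idx].sum()
            ll += beta * xs - d * np.log(s0[i])
            mean1 = s1[i] / s0[i]
            grad += xs - d * mean1
            info += d * (s2[i] / s0[i] - mean1 ** 2)
        i = j
    return ll, grad, info


def cox_partial_loglik(beta: float, time, event, x) -> float:
    return _cox_loglik_parts(beta, time, event, x)[0]


def cox_fit(time, event, x, stratifier: str = "", max_iter: int = 50, tol: float = 1e-8) -> SurvivalFit:
    """Single-covariate Cox PH fit by Newton-Raphson (Breslow ties).

    ``x`` may be a binary group indicator (e.g. the median split) or a
    continuous covariate. Monotone likelihood (complete separation) is
    flagged and the CI reported as unbounded.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=int)
    xv = np.asarray(x, dtype=np.float64)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    uniq = np.unique(xv)
    if len(uniq) < 2:
        raise ValueError("covariate is constant")
    if len(uniq) == 2:
        for u in uniq:
            if event[xv == u].sum() < 1:
                raise ValueError("each group needs >= 1 event")
    beta, converged, separation = 0.0, False, False
    for _ in range(max_iter):
        _, grad, info = _cox_loglik_parts(beta, time, event, xv)
        if info <= 0:
            separation = True
            break
        step = grad / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(grad) < tol:
            converged = True
            break
        if abs(beta) > 15:
            separation = True
            break
    _, _, info = _cox_loglik_parts(beta, time, event, xv)
    se = 1.0 / np.sqrt(info) if info > 0 and not separation else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else np.inf
    p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    lo, hi = (np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)) \
        if np.isfinite(se) else (0.0, np.inf)
    if separation:
        warnings.warn("monotone partial likelihood (complete separation); CI unbounded")
    return SurvivalFit(coef=float(beta), hr=float(np.exp(beta)), se=float(se),
                       ci_low=float(lo), ci_high=float(hi), p=float(p), n=len(time),
                       n_events=int(event.sum()), converged=converged,
                       separation=separation, stratifier=stratifier)


def run_comparisons(table: pd.DataFrame, design: list[dict]) -> pd.DataFrame:
    """Execute a list of contrasts against a patient metric table.

    Each design entry is a dict with keys:
      - metric: column of ``table``
      - kind: "group" (unpaired, between ``groups`` of ``group_col``) or
        "paired" (within-patient, between ``times`` of ``time_col``)
      - family: label; Holm adjustment is applied within each family.
    """
    rows = []
    for spec in design:
        metric = spec["metric"]
        if metric not in table.columns:
            raise ValueError(f"unknown metric column {metric!r}")
        family = spec.get("family", "default")
        if spec["kind"] == "group":
            gcol = spec.get("group_col", "group")
            ga, gb = spec["groups"]
            sub = table
            if "timepoint" in table.columns and spec.get("timepoint") is not None:
                sub = table[table["timepoint"] == spec["timepoint"]]
            a = sub.loc[sub[gcol] == ga, metric].to_numpy()
            b = sub.loc[sub[gcol] == gb, metric].to_numpy()
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"{metric} {ga} vs {gb}: group with < 2 patients; skipped")
                continue
            res = unpaired_ttest(a, b)
            label = f"{ga} vs {gb}"
        elif spec["kind"] == "paired":
            tcol = spec.get("time_col", "timepoint")
            t0, t1 = spec["times"]
            wide = table.pivot_table(index="patient_id", columns=tcol, values=metric)
            wide = wide.dropna(subset=[t0, t1])
            if len(wide) < 2:
                warnings.warn(f"{metric} {t0} vs {t1}: < 2 complete pairs; skipped")
                continue
            res = paired_ttest(wide[t0].to_numpy(), wide[t1].to_numpy())
            label = f"{t0} vs {t1}"
        else:
            raise ValueError(f"unknown contrast kind {spec['kind']!r}")
        rows.append({"metric": metric, "contrast": label, "family": family,
                     "test": res.test, "statistic": res.statistic, "df": res.df,
                     "n_a": res.n_a, "n_b": res.n_b, "p": res.p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for fam, idx in out.groupby("family").groups.items():
            out.loc[idx, "p_adj"] = holm_adjust(out.loc[idx, "p"].to_numpy())
    return out
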