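"""Nonnegative matrix factorization of the transformed expression matrix
into cell-level pattern weights and marker-level amplitudes.

The factorization minimizes the squared Frobenius reconstruction error
by multiplicative updates from an NNDSVD-style initialization, giving a
deterministic, monotonically improving fit. After convergence each
weight column is rescaled to a maximum of 1 — pattern weights range
from 0 to 1 — with the inverse scale absorbed into the amplitudes so
the reconstruction is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, PanelSpec

_EPS = 1e-12


def _nndsvd_init(X: np.ndarray, k: int, rng: np.random.Generator):
    """Nonnegative double SVD init; zeros filled with small seeded noise."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        nup, nvp = np.linalg.norm(up), np.linalg.norm(vp)
        nun, nvn = np.linalg.norm(un), np.linalg.norm(vn)
        if nup * nvp >= nun * nvn:
            sigma = nup * nvp
            uu, vv = up / max(nup, _EPS), vp / max(nvp, _EPS)
        else:
            sigma = nun * nvn
            uu, vv = un / max(nun, _EPS), vn / max(nvn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * uu
        H[j] = np.sqrt(S[j] * sigma) * vv
    # fill zeros at the scale of the data (NNDSVDa-style) with a small seeded
    # jitter; sqrt(mean) has the same degree-1/2 homogeneity as the SVD
    # factors, keeping the init (and hence the fit) scale-equivariant. A
    # near-zero fill stalls the early HALS sweeps.
    fill = np.sqrt(X.mean())
    W[W <= 0] = fill * rng.uniform(0.9, 1.1, size=int((W <= 0).sum()))
    H[H <= 0] = fill * rng.uniform(0.9, 1.1, size=int((H <= 0).sum()))
    return W, H


def _hals_update(F: np.ndarray, G: np.ndarray, XG: np.ndarray) -> None:
    """One HALS sweep over the columns of F for min ||X - F G^T||_F^2,
    given G^T G and X G. Updates F in place; each column update is the
    exact nonnegative coordinate minimizer, so the objective never
    increases."""
    GtG = G.T @ G
    for j in range(F.shape[1]):
        denom = GtG[j, j]
        if denom <= _EPS:
            continue
        f = F[:, j] + (XG[:, j] - F @ GtG[:, j]) / denom
        F[:, j] = np.maximum(f, 0.0)


class PatternNMF(TransformerMixin, BaseEstimator):
    """Frobenius NMF by hierarchical alternating least squares (HALS).

    Parameters
    ----------
    n_patterns : number of patterns k (default 3).
    max_iter, tol : stopping rule — relative objective change below
        ``tol`` or ``max_iter`` iterations.
    random_state : seed for the initialization's zero fill.

    Fitted attributes: ``components_`` (k x markers amplitudes, with the
    weight-column scale absorbed), ``weights_`` (cells x k, column max
    1), ``scale_`` (the per-pattern maxima divided out),
    ``objective_trace_``, ``n_iter_``, ``reconstruction_err_``.
    """

    def __init__(self, n_patterns: int = 3, max_iter: int = 2000, tol: float = 1e-6,
                 random_state: int = 0):
        self.n_patterns = n_patterns
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if (X < 0).any():
            raise ValueError("NMF requires nonnegative input")
        k = self.n_patterns
        if not (1 <= k <= min(X.shape)):
            raise ValueError(f"n_patterns must be in [1, min(n_cells, n_markers)]")
        rng = np.random.default_rng(self.random_state)
        W, H = _nndsvd_init(X, k, rng)
        normX2 = (X ** 2).sum()
        trace = []
        prev = None
        Ht = np.ascontiguousarray(H.T)
        for it in range(self.max_iter):
            _hals_update(W, Ht, X @ Ht)
            _hals_update(Ht, W, X.T @ W)
            H = Ht.T
            obj = normX2 - 2.0 * np.sum(W * (X @ Ht)) + np.sum((W.T @ W) * (H @ H.T))
            obj = max(obj, 0.0)
            trace.append(obj)
            if prev is not None and prev > 0 and (prev - obj) / prev < self.tol:
                break
            prev = obj
        self.n_iter_ = len(trace)
        self.objective_trace_ = np.asarray(trace)
        # absorb the max-1 weight scaling into the amplitudes
        scale = W.max(axis=0)
        safe = np.where(scale > 0, scale, 1.0)
        W = W / safe
        H = H * safe[:, None]
        self.components_ = H
        self.weights_ = W
        self.scale_ = scale
        self.reconstruction_err_ = float(np.linalg.norm(X - W @ H) / max(np.sqrt(normX2), _EPS))
        return W

    def transform(self, X, n_iter: int = 200):
        """Weights for new cells under the fitted amplitudes (HALS
        nonnegative least squares with the amplitudes fixed)."""
        X = np.asarray(X, dtype=np.float64)
        Ht = np.ascontiguousarray(self.components_.T)
        W = np.zeros((X.shape[0], Ht.shape[1]))
        XHt = X @ Ht
        for _ in range(n_iter):
            _hals_update(W, Ht, XHt)
        return W

    def inverse_transform(self, W):
        return np.asarray(W) @ self.components_


@dataclass
class PatternModel:
    """Fitted pattern set: amplitudes (patterns x markers), weights
    (cells x patterns, max 1 per column), labels and fit diagnostics."""

    amplitudes: pd.DataFrame
    weights: pd.DataFrame
    k: int
    labels: list[str]
    objective_trace: np.ndarray
    seed: int
    n_iter: int
    tol: float
    cofactor: float | None = None
    reconstruction_err: float | None = None

    def labeled(self, labels: list[str]) -> "PatternModel":
        amp = self.amplitudes.copy()
        wt = self.weights.copy()
        amp.index = labels
        wt.columns = labels
        return PatternModel(amplitudes=amp, weights=wt, k=self.k, labels=labels,
                            objective_trace=self.objective_trace, seed=self.seed,
                            n_iter=self.n_iter, tol=self.tol, cofactor=self.cofactor,
                            reconstruction_err=self.reconstruction_err)


def fit_patterns(m: ExpressionMatrix, k: int = 3, seed: int = 0, n_iter: int = 2000,
                 tol: float = 1e-6) -> PatternModel:
    """Factorize a transformed cohort matrix into k patterns."""
    if m.scale != "transformed":
        raise ValueError("NMF expects the transformed (arcsinh) scale")
    est = PatternNMF(n_patterns=k, max_iter=n_iter, tol=tol, random_state=seed)
    W = est.fit_transform(m.values)
    labels = [f"pattern{i + 1}" for i in range(k)]
    return PatternModel(
        amplitudes=pd.DataFrame(est.components_, index=labels, columns=m.markers),
        weights=pd.DataFrame(W, columns=labels),
        k=k, labels=labels, objective_trace=est.objective_trace_, seed=seed,
        n_iter=est.n_iter_, tol=tol, cofactor=m.cofactor,
        reconstruction_err=est.reconstruction_err_)


def annotate_patterns(p: PatternModel, panel: PanelSpec) -> PatternModel:
    """Name each pattern after the marker program with the highest mean
    z-scored amplitude over its signature markers."""
    if not panel.programs:
        raise ValueError("panel defines no marker programs")
    amp = p.amplitudes
    sd = amp.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (amp - amp.mean(axis=0)) / sd
    labels, used = [], {}
    for row in amp.index:
        scores = {prog: z.loc[row, [mk for mk in sigs if mk in amp.columns]].mean()
                  for prog, sigs in panel.programs.items()
                  if any(mk in amp.columns for mk in sigs)}
        if not scores:
            raise ValueError("no program signature markers present among amplitudes")
        best = max(sorted(scores), key=lambda pr: scores[pr])
        if best in used:
            used[best] += 1
            warnings.warn(f"program {best!r} maps to multiple patterns; suffixing")
            labels.append(f"{best}_{used[best]}")
        else:
            used[best] = 1
            labels.append(best)
    return p.labeled(labels)


def reconstruction_error(p: PatternModel, m: ExpressionMatrix) -> float:
    """Relative Frobenius error ||X - WH|| / ||X||."""
    X = m.values
    approx = p.weights.to_numpy() @ p.amplitudes.to_numpy()
    if approx.shape != X.shape:
        raise ValueError("model and matrix shapes do not conform")
    denom = np.linalg.norm(X)
    return float(np.linalg.norm(X - approx) / denom) if denom > 0 else 0.0
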