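"""Principal-graph trajectory inference and pseudotime.

The principal graph is k-means centroids in PC space joined by a
Euclidean minimum spanning tree; each cell is projected to its nearest
point on any tree edge, and pseudotime is the geodesic distance along
the tree from a naive origin leaf to that projected point. A first-PC
ordering is provided as an independent second method for concordance
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .embed import Embedding
from .io import ExpressionMatrix, PanelSpec
from .stats import bh_adjust


class PrincipalGraphTrajectory(BaseEstimator):
    """k-means + MST principal graph with geodesic pseudotime.

    Parameters
    ----------
    n_nodes : number of k-means centroids (graph nodes).
    rescale : if True, pseudotime is rescaled to max 1.
    random_state : seed for the k-means initialization.

    Fitted attributes: ``node_positions_`` (nodes x d), ``edges_``
    (list of (i, j, length)), ``cell_edge_``, ``cell_offset_``,
    ``node_labels_``, ``origin_`` and, after ``compute_pseudotime``,
    ``pseudotime_``.
    """

    def __init__(self, n_nodes: int = 50, rescale: bool = False, random_state: int = 0):
        self.n_nodes = n_nodes
        self.rescale = rescale
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        if self.n_nodes >= n:
            raise ValueError("n_nodes must be < number of cells")
        n_unique = np.unique(X, axis=0).shape[0]
        k = min(self.n_nodes, n_unique)
        if k == 1:
            # degenerate: all cells identical -> single-node trajectory
            self.node_positions_ = X[:1].copy()
            self.edges_ = []
            self.node_labels_ = np.zeros(n, dtype=int)
            self.cell_edge_ = np.full(n, -1)
            self.cell_offset_ = np.zeros(n)
            self._proj_node = np.zeros(n, dtype=int)
            return self
        km = KMeans(n_clusters=k, n_init=10, random_state=self.random_state).fit(X)
        self.node_positions_ = km.cluster_centers_
        self.node_labels_ = km.labels_
        d2 = ((self.node_positions_[:, None, :] - self.node_positions_[None, :, :]) ** 2).sum(-1)
        mst = minimum_spanning_tree(csr_matrix(np.sqrt(d2)))
        rows, cols = mst.nonzero()
        self.edges_ = [(int(i), int(j), float(mst[i, j])) for i, j in zip(rows, cols)]
        self._project_cells(X)
        return self

    def _project_cells(self, X):
        """Project each cell to its nearest point on any edge segment."""
        n = X.shape[0]
        best_d2 = np.full(n, np.inf)
        self.cell_edge_ = np.zeros(n, dtype=int)
        self.cell_offset_ = np.zeros(n)
        for e, (i, j, length) in enumerate(self.edges_):
            a, b = self.node_positions_[i], self.node_positions_[j]
            ab = b - a
            denom = float(ab @ ab)
            s = np.clip((X - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(n)
            proj = a + s[:, None] * ab
            d2 = ((X - proj) ** 2).sum(axis=1)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            self.cell_edge_[better] = e
            self.cell_offset_[better] = s[better] * length
        self.projection_residual_ = np.sqrt(best_d2)

    def _check_fitted(self):
        if not hasattr(self, "node_positions_"):
            raise ValueError("trajectory not fitted")

    def leaves(self) -> list[int]:
        self._check_fitted()
        if not self.edges_:
            return [0]
        deg = np.zeros(len(self.node_positions_), dtype=int)
        for i, j, _ in self.edges_:
            deg[i] += 1
            deg[j] += 1
        return [int(v) for v in np.where(deg == 1)[0]]

    def select_origin(self, naive_score: np.ndarray) -> int:
        """Pick the leaf whose assigned cells have the highest mean naive
        score; ties break toward the lower node id."""
        self._check_fitted()
        leaves = self.leaves()
        means = []
        for v in leaves:
            mask = self.node_labels_ == v
            means.append(float(np.mean(naive_score[mask])) if mask.any() else -np.inf)
        best = max(means)
        winners = [v for v, s in zip(leaves, means) if np.isclose(s, best, rtol=0, atol=1e-12)]
        if len(winners) > 1:
            warnings.warn("origin tie between leaves; choosing the lowest node id")
        self.origin_ = min(winners)
        return self.origin_

    def compute_pseudotime(self) -> np.ndarray:
        """Geodesic distance along the tree from the origin to each cell's
        projected point; 0 at the origin."""
        self._check_fitted()
        if not hasattr(self, "origin_"):
            raise ValueError("origin not set; call select_origin or set origin_")
        n_nodes = len(self.node_positions_)
        if not self.edges_:
            self.pseudotime_ = np.zeros(len(self.cell_offset_))
            return self.pseudotime_
        W = np.zeros((n_nodes, n_nodes))
        for i, j, length in self.edges_:
            W[i, j] = W[j, i] = length
        node_dist = shortest_path(csr_matrix(W), indices=self.origin_)
        pt = np.empty(len(self.cell_edge_))
        for e, (i, j, length) in enumerate(self.edges_):
            mask = self.cell_edge_ == e
            if mask.any():
                s = self.cell_offset_[mask]
                pt[mask] = np.minimum(node_dist[i] + s, node_dist[j] + (length - s))
        if self.rescale and pt.max() > 0:
            pt = pt / pt.max()
        self.pseudotime_ = pt
        return pt


@dataclass
class TrendFit:
    marker: str
    grid: np.ndarray
    fitted: np.ndarray
    bandwidth: float


def naive_marker_score(m: ExpressionMatrix, panel: PanelSpec) -> np.ndarray:
    """Per-cell mean of z-scored naive-marker expression."""
    cols = [m.marker_index(mk) for mk in sorted(panel.naive_markers) if mk in m.markers]
    if not cols:
        raise ValueError("no naive markers present in the matrix; supply an explicit origin")
    sub = m.values[:, cols]
    sd = sub.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return ((sub - sub.mean(axis=0)) / sd).mean(axis=1)


def fit_principal_graph(e: Embedding, n_nodes: int = 50, seed: int = 0) -> PrincipalGraphTrajectory:
    return PrincipalGraphTrajectory(n_nodes=n_nodes, random_state=seed).fit(e.scores)


def select_origin(t: PrincipalGraphTrajectory, m: ExpressionMatrix, panel: PanelSpec,
                  origin: int | None = None) -> PrincipalGraphTrajectory:
    if origin is not None:
        t.origin_ = int(origin)
        return t
    t.select_origin(naive_marker_score(m, panel))
    return t


def compute_pseudotime(t: PrincipalGraphTrajectory) -> np.ndarray:
    return t.compute_pseudotime()


def fit_marker_trends(pseudotime: np.ndarray, m: ExpressionMatrix, markers: list[str] | None = None,
                      bandwidth: float | None = None, n_grid: int = 100) -> list[TrendFit]:
    """Tri-cube-weighted local mean of each marker along pseudotime."""
    pt = np.asarray(pseudotime, dtype=np.float64)
    if len(pt) < 20:
        raise ValueError("need >= 20 cells for trend fitting")
    if markers is None:
        markers = m.markers
    span = pt.max() - pt.min()
    bw = bandwidth if bandwidth is not None else 0.15 * (span if span > 0 else 1.0)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(pt.min(), pt.max(), n_grid)
    dist = np.abs(grid[:, None] - pt[None, :])
    w = np.clip(1.0 - (dist / bw) ** 3, 0.0, None) ** 3
    empty = w.sum(axis=1) == 0
    if empty.any():  # fall back to nearest cell where the window is empty
        w[empty, np.argmin(dist[empty], axis=1)] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    fits = []
    for mk in markers:
        y = m.values[:, m.marker_index(mk)]
        fits.append(TrendFit(marker=mk, grid=grid, fitted=w @ y, bandwidth=bw))
    return fits


def comp1_ordering(e: Embedding, m: ExpressionMatrix, panel: PanelSpec) -> np.ndarray:
    """First-PC pseudotime, oriented so naive cells sit at low values and
    shifted to start at 0."""
    pc1 = e.scores[:, 0].copy()
    score = naive_marker_score(m, panel)
    if np.corrcoef(pc1, score)[0, 1] > 0:
        pc1 = -pc1
    return pc1 - pc1.min()


def ordering_concordance(orderings: dict[str, np.ndarray],
                         pattern_weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlations (orderings vs orderings and, if
    given, vs pattern weights) with BH-adjusted p-values."""
    series = dict(orderings)
    if pattern_weights is not None:
        for col in pattern_weights.columns:
            series[str(col)] = np.asarray(pattern_weights[col])
    names = list(series)
    n_len = {len(v) for v in series.values()}
    if len(n_len) != 1:
        raise ValueError("all vectors must have equal length")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho, p = spearmanr(series[names[i]], series[names[j]])
            rows.append({"a": names[i], "b": names[j], "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
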