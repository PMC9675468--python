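"""Dimension reduction, neighbor graphs, Leiden clustering and cluster
summaries — the discrete baseline that continuous state metrics are
contrasted with."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, PanelSpec


class SignFixedPCA(TransformerMixin, BaseEstimator):
    """PCA with a deterministic sign convention: each loading vector is
    flipped so its largest-magnitude entry is positive, making scores
    reproducible across runs and row permutations."""

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if self.n_components > X.shape[1]:
            raise ValueError(f"n_components={self.n_components} exceeds n_features={X.shape[1]}")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(X)
        comp = self._pca.components_
        flip = np.sign(comp[np.arange(comp.shape[0]), np.argmax(np.abs(comp), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comp * flip[:, None]
        self.mean_ = self._pca.mean_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=np.float64) - self.mean_) @ self.components_.T

    def inverse_transform(self, S):
        return np.asarray(S) @ self.components_ + self.mean_


@dataclass
class Embedding:
    """PC scores (cells x d), explained-variance fractions and loadings."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    mean: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    cluster_marker_means: pd.DataFrame | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def named_labels(self) -> np.ndarray:
        if not self.annotations:
            raise ValueError("clusters not annotated yet")
        return np.asarray([self.annotations[c] for c in self.labels])


def pca_reduce(m: ExpressionMatrix, d: int = 10) -> Embedding:
    """Reduce a transformed matrix to d principal components."""
    if m.scale != "transformed":
        raise ValueError("PCA expects the transformed (arcsinh) scale")
    est = SignFixedPCA(n_components=d).fit(m.values)
    return Embedding(scores=est.transform(m.values),
                     explained_variance_ratio=est.explained_variance_ratio_,
                     components=est.components_, mean=est.mean_)


def knn_graph(e: Embedding | np.ndarray, k_neighbors: int = 20) -> igraph.Graph:
    """Undirected kNN graph with shared-neighbor (Jaccard) edge weights."""
    X = e.scores if isinstance(e, Embedding) else np.asarray(e)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, ind = nn.kneighbors(X)
    neigh = [set(row[1:]) for row in ind]  # drop self
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in ind[i, 1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            edges.append((a, b))
            weights.append(inter / union if union else 0.0)
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    return g


def leiden_cluster(graph: igraph.Graph, resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Leiden communities on a weighted graph, relabeled by decreasing size.

    Uses the resolution-parameterized modularity objective
    (RBConfiguration); resolution 1.0 is plain modularity.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    raw = np.asarray(part.membership)
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.asarray([remap[c] for c in raw])
    return ClusterAssignment(labels=labels)


def _cluster_marker_means(labels: np.ndarray, m: ExpressionMatrix) -> pd.DataFrame:
    df = pd.DataFrame(m.values, columns=m.markers)
    return df.groupby(pd.Series(labels, name="cluster")).mean()


def annotate_clusters(c: ClusterAssignment, m: ExpressionMatrix, panel: PanelSpec) -> ClusterAssignment:
    """Name each cluster after the marker program whose signature markers
    have the highest mean z-scored expression across clusters."""
    if not panel.programs:
        raise ValueError("panel defines no marker programs")
    means = _cluster_marker_means(c.labels, m)
    sd = means.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (means - means.mean(axis=0)) / sd if len(means) > 1 else means * 0.0
    annotations: dict = {}
    used: dict = {}
    for cl in means.index:
        scores = {prog: z.loc[cl, [mk for mk in sigs if mk in z.columns]].mean()
                  for prog, sigs in panel.programs.items()
                  if any(mk in z.columns for mk in sigs)}
        if not scores:
            raise ValueError("no program signature markers present in the matrix")
        best = max(sorted(scores), key=lambda p: scores[p])
        if best in used:
            used[best] += 1
            warnings.warn(f"program {best!r} maps to multiple clusters; suffixing")
            name = f"{best}_{used[best]}"
        else:
            used[best] = 1
            name = best
        annotations[cl] = name
    return replace(c, cluster_marker_means=means, annotations=annotations)


def cluster_proportions(c: ClusterAssignment, cell_meta: pd.DataFrame,
                        by: str = "patient_id") -> pd.DataFrame:
    """Per-patient cluster composition; rows sum to 1."""
    if cell_meta[by].isna().any():
        raise ValueError(f"cells with missing {by}")
    names = c.named_labels if c.annotations else c.labels
    tab = pd.crosstab(cell_meta[by], pd.Series(names, name="cluster"))
    return tab.div(tab.sum(axis=1), axis=0)
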