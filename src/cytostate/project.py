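"""Transfer learning: project new cohorts onto learned marker amplitudes.

Pattern weights in a target data set are obtained per cell by
nonnegative least squares against the source amplitude matrix,
restricted to the markers the two panels share (after channel-dialect
normalization). Because the source model absorbs its weight scaling
into the amplitudes, projected weights land directly on the source
weight scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, normalize_marker_name
from .patterns import PatternModel
from .stats import holm_adjust, patient_means, unpaired_ttest


@dataclass
class ProjectionResult:
    weights: pd.DataFrame
    shared_markers: list[str]
    dropped_source_markers: list[str]
    unmatched_target_markers: list[str]
    residuals: np.ndarray


def intersect_panels(source_amplitudes: pd.DataFrame, target_markers: list[str],
                     min_shared: int = 3):
    """Restrict amplitude columns to the shared panel, in target order.

    Returns (restricted amplitudes, shared markers, report dict).
    """
    src_norm = {normalize_marker_name(c): c for c in source_amplitudes.columns}
    tgt_norm = [normalize_marker_name(t) for t in target_markers]
    shared = [t for t in tgt_norm if t in src_norm]
    dropped = sorted(set(src_norm) - set(shared))
    unmatched = sorted(set(tgt_norm) - set(src_norm))
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared markers (< {min_shared}); "
            f"dropped source markers: {dropped}; unmatched target markers: {unmatched}")
    restricted = source_amplitudes[[src_norm[t] for t in shared]].copy()
    restricted.columns = shared
    report = {"shared": shared, "dropped_source": dropped, "unmatched_target": unmatched}
    return restricted, shared, report


def project_weights(restricted_amplitudes: pd.DataFrame, target: ExpressionMatrix,
                    rescale: str = "source") -> ProjectionResult:
    """Per-cell NNLS of target expression onto the amplitude rows.

    ``rescale='source'`` keeps weights on the source model's scale
    (amplitudes already carry the source scaling); ``'target'``
    additionally max-scales each weight column within the target cohort.
    """
    if target.scale != "transformed":
        raise ValueError("target must be on the transformed (arcsinh) scale")
    shared = [normalize_marker_name(c) for c in restricted_amplitudes.columns]
    cols = [target.markers.index(mk) for mk in shared]
    X = target.values[:, cols]
    if (X < 0).any():
        raise ValueError("target values must be nonnegative")
    A = restricted_amplitudes.to_numpy(dtype=np.float64)  # k x m
    if np.linalg.matrix_rank(A) < A.shape[0]:
        warnings.warn("restricted amplitudes are rank-deficient; NNLS returns a minimum-norm-style solution")
    k = A.shape[0]
    W = np.empty((X.shape[0], k))
    resid = np.empty(X.shape[0])
    At = A.T
    for i in range(X.shape[0]):
        W[i], resid[i] = nnls(At, X[i])
    if rescale == "target":
        colmax = W.max(axis=0)
        W = W / np.where(colmax > 0, colmax, 1.0)
    elif rescale != "source":
        raise ValueError("rescale must be 'source' or 'target'")
    weights = pd.DataFrame(W, columns=list(restricted_amplitudes.index))
    return ProjectionResult(weights=weights, shared_markers=shared,
                            dropped_source_markers=[], unmatched_target_markers=[],
                            residuals=resid)


class PatternProjector(TransformerMixin, BaseEstimator):
    """Project expression onto a fixed source amplitude matrix.

    Parameters: ``model`` (a fitted PatternModel), ``min_shared`` shared
    marker floor, ``rescale`` ('source' or 'target').
    """

    def __init__(self, model: PatternModel, min_shared: int = 3, rescale: str = "source"):
        self.model = model
        self.min_shared = min_shared
        self.rescale = rescale

    def fit(self, target: ExpressionMatrix, y=None):
        if self.model.cofactor is not None and target.cofactor is not None \
                and self.model.cofactor != target.cofactor:
            raise ValueError(
                f"target transformed with cofactor {target.cofactor}, "
                f"source model used {self.model.cofactor}")
        restricted, shared, report = intersect_panels(
            self.model.amplitudes, target.markers, min_shared=self.min_shared)
        self.restricted_amplitudes_ = restricted
        self.shared_markers_ = shared
        self.report_ = report
        return self

    def transform(self, target: ExpressionMatrix) -> ProjectionResult:
        if not hasattr(self, "restricted_amplitudes_"):
            self.fit(target)
        res = project_weights(self.restricted_amplitudes_, target, rescale=self.rescale)
        res.dropped_source_markers = self.report_["dropped_source"]
        res.unmatched_target_markers = self.report_["unmatched_target"]
        return res


def project_cohort(model: PatternModel, target: ExpressionMatrix, min_shared: int = 3,
                   rescale: str = "source") -> ProjectionResult:
    proj = PatternProjector(model, min_shared=min_shared, rescale=rescale).fit(target)
    return proj.transform(target)


def compare_projected_groups(result: ProjectionResult, cell_meta: pd.DataFrame,
                             grouping: str = "group") -> pd.DataFrame:
    """Patient-mean projected weights compared across groups, per pattern,
    with Welch tests and Holm adjustment across patterns."""
    if grouping not in cell_meta.columns:
        raise ValueError(f"grouping column {grouping!r} missing from cell metadata")
    rows = []
    for pat in result.weights.columns:
        pm = patient_means(result.weights[pat].to_numpy(), cell_meta,
                           by=("patient_id",), name="w")
        pm = pm.merge(cell_meta[["patient_id", grouping]].drop_duplicates(), on="patient_id")
        groups = sorted(pm[grouping].dropna().unique())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = pm.loc[pm[grouping] == groups[i], "w"].to_numpy()
                b = pm.loc[pm[grouping] == groups[j], "w"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(f"{pat}: group with < 2 patients; comparison skipped")
                    continue
                res = unpaired_ttest(a, b)
                rows.append({"pattern": pat, "contrast": f"{groups[i]} vs {groups[j]}",
                             "statistic": res.statistic, "df": res.df,
                             "n_a": res.n_a, "n_b": res.n_b, "p": res.p,
                             "mean_a": a.mean(), "mean_b": b.mean()})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = holm_adjust(out["p"].to_numpy())
    return out
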