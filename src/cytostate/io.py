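"""Reading, preprocessing and aggregation of cytometry event tables.

Raw mass-cytometry ion intensities are nonnegative and heavy-tailed; the
standard variance-stabilizing transform is ``asinh(x / cofactor)`` with
cofactor 5. Panels name channels in a "Metal_Isotope_Target" dialect
(e.g. ``Er168Di_CCR7``); marker names are normalized by stripping the
isotope prefix and uppercasing, so panels from different instruments can
be intersected.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._fcs import read_fcs

_ISOTOPE_PREFIX = re.compile(r"^[A-Za-z]{1,2}\d{2,3}Di[_\- ]", re.IGNORECASE)

DEFAULT_COFACTOR = 5.0


def normalize_marker_name(name: str) -> str:
    """Strip a metal/isotope channel prefix and uppercase the target name."""
    return _ISOTOPE_PREFIX.sub("", name.strip()).upper()


@dataclass
class PanelSpec:
    """Marker panel: full marker list, barcode channels to drop, naive
    markers used for trajectory-origin selection, and marker programs
    (program name -> set of signature markers) used for annotation."""

    markers: list[str]
    barcode_markers: set[str] = field(default_factory=set)
    naive_markers: set[str] = field(default_factory=lambda: {"CCR7", "CD45RA"})
    programs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.markers = [normalize_marker_name(m) for m in self.markers]
        self.barcode_markers = {normalize_marker_name(m) for m in self.barcode_markers}
        self.naive_markers = {normalize_marker_name(m) for m in self.naive_markers}
        self.programs = {k: {normalize_marker_name(m) for m in v} for k, v in self.programs.items()}
        if not self.barcode_markers <= set(self.markers):
            raise ValueError("barcode_markers must be a subset of markers")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("markers not unique after dialect normalization")

    def to_json(self, path) -> None:
        obj = {
            "markers": self.markers,
            "barcode_markers": sorted(self.barcode_markers),
            "naive_markers": sorted(self.naive_markers),
            "programs": {k: sorted(v) for k, v in self.programs.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path) -> "PanelSpec":
        obj = json.loads(Path(path).read_text())
        return cls(
            markers=obj["markers"],
            barcode_markers=set(obj.get("barcode_markers", [])),
            naive_markers=set(obj.get("naive_markers", ["CCR7", "CD45RA"])),
            programs={k: set(v) for k, v in obj.get("programs", {}).items()},
        )


@dataclass
class ExpressionMatrix:
    """Cells x markers intensity table with per-cell metadata.

    ``scale`` is ``"raw"`` (ion counts, >= 0) or ``"transformed"``
    (arcsinh); the cofactor used is carried so projection across cohorts
    can enforce matching transforms.
    """

    values: np.ndarray
    markers: list[str]
    cell_meta: pd.DataFrame
    scale: str = "raw"
    cofactor: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("marker list length must match number of columns")
        if len(self.cell_meta) != self.values.shape[0]:
            raise ValueError("cell_meta length must equal number of rows")
        if self.scale not in ("raw", "transformed"):
            raise ValueError("scale must be 'raw' or 'transformed'")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker_index(self, marker: str) -> int:
        return self.markers.index(normalize_marker_name(marker))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.markers)


class ArcsinhTransformer(TransformerMixin, BaseEstimator):
    """Elementwise ``asinh(x / cofactor)`` (stateless; fit is a no-op)."""

    def __init__(self, cofactor: float = DEFAULT_COFACTOR):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        return np.arcsinh(np.asarray(X, dtype=np.float64) / self.cofactor)

    def inverse_transform(self, X):
        return np.sinh(np.asarray(X, dtype=np.float64)) * self.cofactor


def read_sample(path, format: str | None = None, panel: PanelSpec | None = None,
                sample_id: str | None = None) -> ExpressionMatrix:
    """Read one sample's event table (CSV or FCS) as a raw-scale matrix.

    Marker names are dialect-normalized; event order is preserved. When a
    panel is given, every column must resolve against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric columns {list(bad)}")
        values = df.to_numpy(dtype=np.float64)
        names = [normalize_marker_name(c) for c in df.columns]
    elif format == "fcs":
        values, _chan, pns = read_fcs(path)
        names = [normalize_marker_name(n) for n in pns]
    else:
        raise ValueError(f"unsupported format {format!r}")
    if panel is not None:
        unresolvable = [n for n in names if n not in panel.markers]
        if unresolvable:
            raise ValueError(f"{path}: marker names not in panel: {unresolvable}")
    sid = sample_id if sample_id is not None else path.stem
    meta = pd.DataFrame({"sample_id": [sid] * len(values)})
    return ExpressionMatrix(values=values, markers=names, cell_meta=meta, scale="raw")


def arcsinh_transform(m: ExpressionMatrix, cofactor: float = DEFAULT_COFACTOR) -> ExpressionMatrix:
    """Apply the arcsinh transform to a raw-scale matrix."""
    if m.scale != "raw":
        raise ValueError("matrix is already transformed (double-transform refused)")
    tr = ArcsinhTransformer(cofactor=cofactor)
    return replace(m, values=tr.fit(m.values).transform(m.values), scale="transformed", cofactor=cofactor)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Seed per sample from (global seed, sample id) so subsampling does not
    # depend on the order samples are processed in.
    digest = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def subsample_cells(m: ExpressionMatrix, n_per_sample: int = 10_000, seed: int = 0) -> ExpressionMatrix:
    """Retain at most ``n_per_sample`` uniformly chosen cells per sample."""
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    keep_parts = []
    for sid, idx in m.cell_meta.groupby("sample_id", sort=True).groups.items():
        idx = np.asarray(idx)
        if len(idx) > n_per_sample:
            rng = _sample_rng(seed, str(sid))
            idx = np.sort(rng.choice(idx, size=n_per_sample, replace=False))
        keep_parts.append(idx)
    keep = np.sort(np.concatenate(keep_parts))
    return replace(m, values=m.values[keep], cell_meta=m.cell_meta.iloc[keep].reset_index(drop=True))


def drop_barcode_markers(m: ExpressionMatrix, panel: PanelSpec) -> ExpressionMatrix:
    """Remove barcoding channels (e.g. CD45 isotopes), preserving order."""
    keep = [i for i, name in enumerate(m.markers) if name not in panel.barcode_markers]
    if not keep:
        raise ValueError("all markers flagged as barcode channels; >= 1 marker required")
    return replace(m, values=m.values[:, keep], markers=[m.markers[i] for i in keep])


def aggregate_cohort(samples: list[ExpressionMatrix], metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Row-concatenate per-sample matrices and join sample-level metadata."""
    if not samples:
        raise ValueError("no samples to aggregate")
    ref = samples[0].markers
    for s in samples[1:]:
        if s.markers != ref:
            diff = sorted(set(s.markers) ^ set(ref))
            raise ValueError(f"marker-set mismatch across samples; symmetric difference: {diff}")
    scales = {s.scale for s in samples}
    if len(scales) != 1:
        raise ValueError("samples mix raw and transformed scales")
    values = np.vstack([s.values for s in samples])
    meta = pd.concat([s.cell_meta for s in samples], ignore_index=True)
    if metadata is not None:
        cols = [c for c in metadata.columns if c != "sample_id"]
        meta = meta.merge(metadata[["sample_id"] + cols], on="sample_id", how="left", validate="many_to_one")
        if "patient_id" in meta.columns and meta["patient_id"].isna().any():
            missing = sorted(meta.loc[meta["patient_id"].isna(), "sample_id"].unique())
            raise ValueError(f"samples missing from metadata table: {missing}")
    return ExpressionMatrix(values=values, markers=list(ref), cell_meta=meta,
                            scale=samples[0].scale, cofactor=samples[0].cofactor)


def preprocess_cohort(sample_paths: list, metadata: pd.DataFrame, panel: PanelSpec,
                      cofactor: float = DEFAULT_COFACTOR, n_per_sample: int = 10_000,
                      seed: int = 0) -> ExpressionMatrix:
    """Read -> aggregate -> subsample -> drop barcodes -> arcsinh.

    The standard preprocessing chain; returns the transformed cohort
    matrix with per-cell metadata attached.
    """
    samples = [read_sample(p, panel=panel) for p in sample_paths]
    cohort = aggregate_cohort(samples, metadata)
    cohort = subsample_cells(cohort, n_per_sample=n_per_sample, seed=seed)
    cohort = drop_barcode_markers(cohort, panel)
    return arcsinh_transform(cohort, cofactor=cofactor)
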