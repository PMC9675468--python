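"""End-to-end orchestration: preprocess -> embed/cluster -> trajectory ->
patterns -> patient metrics -> statistics, from a single config, with a
manifest tying outputs to parameters and seeds."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .embed import annotate_clusters, cluster_proportions, knn_graph, leiden_cluster, pca_reduce
from .io import PanelSpec, preprocess_cohort
from .patterns import annotate_patterns, fit_patterns
from .stats import patient_means, run_comparisons
from .trajectory import compute_pseudotime, fit_principal_graph, select_origin


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run. Defaults mirror the standard
    workflow: arcsinh cofactor 5, 10,000 cells per sample, 10 PCs,
    kNN 20, Leiden resolution 1.0, 50 trajectory nodes, 3 patterns."""

    input_dir: str
    panel_file: str
    output_dir: str
    metadata_file: str | None = None
    cofactor: float = 5.0
    subsample_n: int = 10_000
    n_pcs: int = 10
    knn: int = 20
    resolution: float = 1.0
    trajectory_nodes: int = 50
    k_patterns: int = 3
    seed: int = 0
    rescale_pseudotime: bool = False
    comparison_design: list = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def validate_config(config: PipelineConfig) -> list[str]:
    """All schema and cross-field checks, reported at once."""
    errors = []
    if not Path(config.input_dir).is_dir():
        errors.append(f"input_dir does not exist: {config.input_dir}")
    if not Path(config.panel_file).is_file():
        errors.append(f"panel file does not exist: {config.panel_file}")
    if config.metadata_file is not None and not Path(config.metadata_file).is_file():
        errors.append(f"metadata file does not exist: {config.metadata_file}")
    if config.cofactor <= 0:
        errors.append("cofactor must be > 0")
    for name in ("subsample_n", "n_pcs", "knn", "trajectory_nodes", "k_patterns"):
        if getattr(config, name) < 1:
            errors.append(f"{name} must be >= 1")
    if not errors and Path(config.panel_file).is_file():
        try:
            panel = PanelSpec.from_json(config.panel_file)
            usable = len(panel.markers) - len(panel.barcode_markers)
            if config.n_pcs > usable:
                errors.append(f"n_pcs={config.n_pcs} exceeds usable markers ({usable})")
            if config.k_patterns > usable:
                errors.append(f"k_patterns={config.k_patterns} exceeds usable markers ({usable})")
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            errors.append(f"panel file invalid: {exc}")
    if not isinstance(config.seed, (int, np.integer)):
        errors.append("seed must be an integer")
    return errors


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; writes CSV artifacts plus a manifest JSON and
    returns the in-memory results keyed by stage."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    panel = PanelSpec.from_json(config.panel_file)
    indir = Path(config.input_dir)
    paths = sorted(list(indir.glob("*.csv")) + list(indir.glob("*.fcs")))
    paths = [p for p in paths if p.name != "metadata.csv"]
    meta_path = config.metadata_file or (indir / "metadata.csv")
    metadata = pd.read_csv(meta_path)

    cohort = _stage("preprocess", lambda: preprocess_cohort(
        paths, metadata, panel, cofactor=config.cofactor,
        n_per_sample=config.subsample_n, seed=config.seed))

    emb = _stage("pca", lambda: pca_reduce(cohort, d=min(config.n_pcs, len(cohort.markers))))

    def _cluster():
        g = knn_graph(emb, k_neighbors=config.knn)
        c = leiden_cluster(g, resolution=config.resolution, seed=config.seed)
        return annotate_clusters(c, cohort, panel) if panel.programs else c
    clusters = _stage("cluster", _cluster)

    def _traj():
        t = fit_principal_graph(emb, n_nodes=min(config.trajectory_nodes, cohort.n_cells - 1),
                                seed=config.seed)
        t.rescale = config.rescale_pseudotime
        select_origin(t, cohort, panel)
        compute_pseudotime(t)
        return t
    traj = _stage("trajectory", _traj)

    def _patterns():
        model = fit_patterns(cohort, k=config.k_patterns, seed=config.seed)
        return annotate_patterns(model, panel) if panel.programs else model
    model = _stage("patterns", _patterns)

    def _metrics():
        table = patient_means(traj.pseudotime_, cohort.cell_meta, name="mean_pseudotime")
        for lbl in model.weights.columns:
            col = patient_means(model.weights[lbl].to_numpy(), cohort.cell_meta,
                                name=f"mean_weight_{lbl}")
            table = table.merge(col.drop(columns=["n_cells", "low_count"]),
                                on=["patient_id", "timepoint"])
        props = cluster_proportions(clusters, cohort.cell_meta)
        props.columns = [f"prop_{c}" for c in props.columns]
        table = table.merge(props.reset_index(), on="patient_id", how="left")
        join_cols = [c for c in ("patient_id", "group", "survival_time", "event", "response")
                     if c in metadata.columns]
        table = table.merge(metadata[join_cols].drop_duplicates("patient_id"),
                            on="patient_id", how="left")
        return table
    table = _stage("metrics", _metrics)

    stats = _stage("stats", lambda: run_comparisons(table, config.comparison_design)) \
        if config.comparison_design else pd.DataFrame()

    # artifacts
    pd.DataFrame({"cell_id": np.arange(cohort.n_cells),
                  "cluster": clusters.labels,
                  "name": clusters.named_labels if clusters.annotations else clusters.labels,
                  "pseudotime": traj.pseudotime_}).to_csv(out / "cells.csv", index=False)
    model.amplitudes.to_csv(out / "amplitudes.csv")
    model.weights.to_csv(out / "weights.csv", index_label="cell_id")
    table.to_csv(out / "patient_metrics.csv", index=False)
    if len(stats):
        stats.to_csv(out / "stats.csv", index=False)
    manifest = {"version": __version__, "config": asdict(config),
                "config_hash": _config_hash(config), "timings_s": timings,
                "n_cells": int(cohort.n_cells), "n_markers": len(cohort.markers)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"cohort": cohort, "embedding": emb, "clusters": clusters, "trajectory": traj,
            "patterns": model, "patient_metrics": table, "stats": stats, "manifest": manifest}
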