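"""Synthetic multi-patient cytometry cohorts with planted continuous state structure.

Each cell carries a latent state t in [0, 1] along a single linear
trajectory (naive at t=0, terminal exhausted/effector state at t=1).
Smooth weight curves map t to k nonnegative pattern weights; expression
on the arcsinh scale is weights x archetype amplitudes plus Gaussian
noise, mapped back to the raw ion scale by sinh. Group and time-point
effects shift the latent-state distribution; patient-level survival is
exponential with log-hazard linked to the patient's mean terminal
pattern weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._fcs import write_fcs
from .io import ExpressionMatrix, normalize_marker_name

DEFAULT_PROGRAMS = {
    "naive": {"CCR7", "CD45RA", "CD28"},
    "preexhaustion": {"CD38", "HLADR", "KI67"},
    "exhaustion": {"TOX", "HELIOS", "PD1"},
}

# Lanthanide-series isotope tags used for the Metal_Isotope_Target channel dialect.
_ISOTOPES = [
    "Y89", "In113", "In115", "La139", "Pr141", "Nd142", "Nd143", "Nd144", "Nd145",
    "Nd146", "Sm147", "Nd148", "Sm149", "Nd150", "Eu151", "Sm152", "Eu153", "Sm154",
    "Gd155", "Gd156", "Gd158", "Tb159", "Gd160", "Dy161", "Dy162", "Dy163", "Dy164",
    "Ho165", "Er166", "Er167", "Er168", "Tm169", "Er170", "Yb171", "Yb172", "Yb173",
    "Yb174", "Lu175", "Yb176", "Bi209",
]


@dataclass
class ArchetypeSet:
    """Planted patterns: labels, amplitude matrix (patterns x markers, arcsinh
    scale) and the signature-marker program behind each pattern."""

    labels: list[str]
    amplitudes: np.ndarray
    marker_names: list[str]
    marker_programs: dict[str, set[str]]

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be nonnegative")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("pattern labels must be unique")
        if self.amplitudes.shape != (len(self.labels), len(self.marker_names)):
            raise ValueError("amplitude shape inconsistent with labels/markers")


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults encode a two-group cross-sectional design: 12 patients per
    group, 5,000 cells per sample, a 30-marker panel with 3 planted
    patterns, a +0.4 latent-state shift in the second group, cell-level
    noise sd 0.1 on the arcsinh scale and patient-level heterogeneity
    sd 0.05 on the latent-state mean.
    """

    n_patients_per_group: int = 12
    groups: tuple = ("A", "B")
    n_cells_per_sample: int = 5000
    n_markers: int = 30
    k_true: int = 3
    state_shift_per_group: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.4})
    timepoints: tuple = ("baseline",)
    paired_timepoint_shift: float = 0.0
    noise_sd: float = 0.1
    patient_effect_sd: float = 0.05
    baseline_state_mean: float = 0.35
    state_concentration: float = 4.0
    survival_link_coef: float = 0.0
    baseline_hazard: float = 0.03
    censor_rate: float = 0.2
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients_per_group, self.n_cells_per_sample, self.n_markers, self.k_true) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")

    def to_json(self, path) -> None:
        obj = {k: (list(v) if isinstance(v, (tuple, set)) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        obj = json.loads(Path(path).read_text())
        for k in ("groups", "timepoints"):
            if k in obj:
                obj[k] = tuple(obj[k])
        return cls(**obj)


@dataclass
class CohortTruth:
    """Ground truth behind a simulated cohort, aligned with the cohort
    matrix rows: per-cell latent state and pattern weights, plus the
    per-patient table of true metric means and survival."""

    latent_state: np.ndarray
    weights: np.ndarray
    patient_table: pd.DataFrame
    archetypes: ArchetypeSet


def make_archetypes(panel_size: int, k: int, program_spec: dict | None = None,
                    seed: int = 0, marker_names: list[str] | None = None) -> ArchetypeSet:
    """Build k nonnegative amplitude rows over a panel of panel_size markers.

    Each pattern's signature markers get a high amplitude (uniform in
    [2, 3] on the arcsinh scale) that is strictly maximal across
    patterns; everything else gets a small baseline (uniform in
    [0.02, 0.4]).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if program_spec is None:
        program_spec = {name: set(m) for name, m in list(DEFAULT_PROGRAMS.items())[:k]}
    if len(program_spec) != k:
        raise ValueError(f"program_spec must define exactly k={k} programs")
    labels = list(program_spec)
    sig_sets = [set(normalize_marker_name(m) for m in program_spec[p]) for p in labels]
    all_sigs: list[str] = []
    for s in sig_sets:
        if not s:
            raise ValueError("every program needs >= 1 signature marker")
        for m in sorted(s):
            if m in all_sigs:
                raise ValueError(f"signature marker {m} assigned to more than one program")
            all_sigs.append(m)
    if panel_size < len(all_sigs):
        raise ValueError("panel_size smaller than the total number of signature markers")

    if marker_names is None:
        fillers = [f"MARKER{i + 1}" for i in range(panel_size - len(all_sigs))]
        marker_names = all_sigs + fillers
    else:
        marker_names = [normalize_marker_name(m) for m in marker_names]
        if len(marker_names) != panel_size or not set(all_sigs) <= set(marker_names):
            raise ValueError("marker_names must cover all signature markers and have length panel_size")

    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.02, 0.4, size=(k, panel_size))
    col = {m: j for j, m in enumerate(marker_names)}
    for i, sigs in enumerate(sig_sets):
        for m in sigs:
            amp[i, col[m]] = rng.uniform(2.0, 3.0)
    programs = {p: s for p, s in zip(labels, sig_sets)}
    return ArchetypeSet(labels=labels, amplitudes=amp, marker_names=marker_names, marker_programs=programs)


def sample_latent_states(n_cells: int, group_shift: float = 0.0, timepoint_shift: float = 0.0,
                         seed: int = 0, base_mean: float = 0.35, concentration: float = 4.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw latent states t in [0, 1] from a Beta distribution whose mean
    increases with group_shift + timepoint_shift."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = float(np.clip(base_mean + group_shift + timepoint_shift, 0.02, 0.98))
    t = rng.beta(mu * concentration, (1.0 - mu) * concentration, size=n_cells)
    return np.clip(t, 0.0, 1.0)


def states_to_weights(t: np.ndarray, k: int, bump_width: float = 0.16) -> np.ndarray:
    """Map latent states to k pattern weights in [0, 1].

    Pattern 1 decreases as (1-t)^2, the terminal pattern increases as
    t^2, and interior patterns are Gaussian bumps centered on an even
    grid — transient mid-trajectory programs.
    """
    t = np.asarray(t, dtype=np.float64)
    if ((t < 0) | (t > 1)).any():
        raise ValueError("latent states must lie in [0, 1]")
    if k < 2:
        raise ValueError("k must be >= 2")
    W = np.empty((t.shape[0], k))
    W[:, 0] = (1.0 - t) ** 2
    W[:, -1] = t ** 2
    for j in range(1, k - 1):
        center = j / (k - 1)
        W[:, j] = np.exp(-((t - center) ** 2) / (2.0 * bump_width ** 2))
    return np.clip(W, 0.0, 1.0)


def simulate_cohort(config: CohortConfig, archetypes: ArchetypeSet | None = None
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Simulate a cohort; returns (raw-scale matrix, sample metadata, truth)."""
    if archetypes is None:
        archetypes = make_archetypes(config.n_markers, config.k_true, seed=config.seed)
    if archetypes.amplitudes.shape != (config.k_true, config.n_markers):
        raise ValueError("archetypes inconsistent with config (k_true, n_markers)")
    rng = np.random.default_rng(config.seed)
    k = config.k_true

    blocks, meta_rows, t_all, w_all = [], [], [], []
    patient_rows = []
    tp_shifts = {tp: i * config.paired_timepoint_shift for i, tp in enumerate(config.timepoints)}
    for group in config.groups:
        gshift = config.state_shift_per_group.get(group, 0.0)
        for p in range(config.n_patients_per_group):
            pid = f"{group}{p + 1:02d}"
            peffect = rng.normal(0.0, config.patient_effect_sd)
            pat_mean_w = None
            for tp in config.timepoints:
                t = sample_latent_states(
                    config.n_cells_per_sample, gshift + peffect, tp_shifts[tp],
                    base_mean=config.baseline_state_mean,
                    concentration=config.state_concentration, rng=rng)
                W = states_to_weights(t, k)
                Y = W @ archetypes.amplitudes
                if config.noise_sd > 0:
                    Y = Y + rng.normal(0.0, config.noise_sd, size=Y.shape)
                raw = np.maximum(np.sinh(Y) * config.cofactor, 0.0)
                sid = f"{pid}_{tp}"
                blocks.append(raw)
                t_all.append(t)
                w_all.append(W)
                n = config.n_cells_per_sample
                meta_rows.append(pd.DataFrame({
                    "sample_id": [sid] * n, "patient_id": [pid] * n,
                    "group": [group] * n, "timepoint": [tp] * n, "batch": ["b1"] * n,
                }))
                if pat_mean_w is None:
                    pat_mean_w = W.mean(axis=0)  # baseline time point drives survival
            haz = config.baseline_hazard * np.exp(config.survival_link_coef * pat_mean_w[-1])
            surv_t = rng.exponential(1.0 / haz)
            event = 1
            if config.censor_rate > 0 and rng.uniform() < config.censor_rate:
                surv_t *= rng.uniform()
                event = 0
            patient_rows.append({
                "patient_id": pid, "group": group,
                "true_mean_state": float(np.mean(t_all[-1])),
                **{f"true_mean_weight_{lbl}": float(pat_mean_w[i]) for i, lbl in enumerate(archetypes.labels)},
                "survival_time": float(surv_t), "event": event,
            })

    values = np.vstack(blocks)
    cell_meta = pd.concat(meta_rows, ignore_index=True)
    matrix = ExpressionMatrix(values=values, markers=list(archetypes.marker_names),
                              cell_meta=cell_meta, scale="raw")
    patient_table = pd.DataFrame(patient_rows)
    metadata = (cell_meta.drop_duplicates("sample_id")[["sample_id", "patient_id", "group", "timepoint", "batch"]]
                .merge(patient_table[["patient_id", "survival_time", "event"]], on="patient_id")
                .reset_index(drop=True))
    truth = CohortTruth(latent_state=np.concatenate(t_all), weights=np.vstack(w_all),
                        patient_table=patient_table, archetypes=archetypes)
    return matrix, metadata, truth


def _channel_names(markers: list[str], dialect: str) -> list[str]:
    if dialect == "plain":
        return list(markers)
    if dialect == "metal":
        if len(markers) > len(_ISOTOPES):
            raise ValueError("panel larger than the available isotope tag list")
        return [f"{_ISOTOPES[i]}Di_{m}" for i, m in enumerate(markers)]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_cohort(matrix: ExpressionMatrix, metadata: pd.DataFrame, dir_path,
                 format: str = "csv", dialect: str = "plain") -> list[Path]:
    """Write one event file per sample plus a metadata CSV; returns paths."""
    if format not in ("csv", "fcs"):
        raise ValueError(f"unsupported format {format!r}")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    channels = _channel_names(matrix.markers, dialect)
    paths = []
    for sid, idx in matrix.cell_meta.groupby("sample_id", sort=True).groups.items():
        block = matrix.values[np.asarray(idx)]
        path = out / f"{sid}.{format}"
        if format == "csv":
            # %.17g round-trips float64 exactly
            pd.DataFrame(block, columns=channels).to_csv(path, index=False, float_format="%.17g")
        else:
            write_fcs(path, block, channel_names=channels, marker_names=channels)
        paths.append(path)
    meta_path = out / "metadata.csv"
    metadata.to_csv(meta_path, index=False)
    return paths + [meta_path]
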