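"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
network metrics -> group statistics, as one reproducible, seeded run.

A :class:`RunConfig` (serializable to a single JSON document) plus a
master seed determines every artifact byte-for-byte. Per-stage child
seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from .connectivity import epochs_to_band_matrices
from .montage import DEFAULT_MONTAGE
from .network import SPARSITY_LEVELS, ThresholdProfile, metrics_over_thresholds
from .preprocessing import (
    BAND_BY_NAME,
    TASKS,
    bandpass_filter,
    baseline_correct,
    epoch,
    mirror_lateral,
    notch_filter,
    rereference_linked_ears,
    resample,
)
from .stats import compare_cohort, correlate_mas
from .synthetic import SimulatedSubject, default_coupling, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one analysis run, serializable to JSON."""

    seed: int = 0
    # simulation block
    n_per_group: int = 8
    patient_attenuation: float = 0.3
    n_trials: int = 20
    fs: float = 1000.0
    gap_s: float = 2.0
    noise_sd: float = 7.0
    mixing_strength: float = 0.2
    coupling_bands: tuple[str, ...] = ("alpha", "beta")
    right_affected_fraction: float = 1 / 8
    # preprocessing
    bandpass: tuple[float, float] | None = (0.1, 45.0)
    notch: tuple[float, float] | None = (49.0, 51.0)
    resample_to: float | None = 500.0
    tasks: tuple[str, ...] = TASKS
    # connectivity
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    window_s: float = 0.4
    hop_s: float = 0.2
    per_window: bool = False
    # network
    sparsity_levels: tuple[float, ...] = SPARSITY_LEVELS
    n_realizations: int = 100
    with_sw: bool = True
    # statistics
    gate_alpha: float = 0.05
    fdr_scope: str = "run"
    mas_col: str = "mas_upper"

    def __post_init__(self) -> None:
        for b in tuple(self.bands) + tuple(self.coupling_bands):
            if b not in BAND_BY_NAME:
                raise ValueError(f"unknown band name {b!r}")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        if self.fdr_scope not in ("run", "task"):
            raise ValueError("fdr_scope must be 'run' or 'task'")
        if self.mas_col not in ("mas_upper", "mas_hand"):
            raise ValueError("mas_col must be 'mas_upper' or 'mas_hand'")
        if not 0 <= self.patient_attenuation <= 1:
            raise ValueError("patient_attenuation must lie in [0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("coupling_bands", "tasks", "bands", "sparsity_levels",
                    "bandpass", "notch"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def preprocess_subject(subject: SimulatedSubject, cfg: RunConfig) -> dict:
    """Filter, resample, re-reference, epoch, baseline, mirror one subject.

    Returns task -> EpochSet over the 19 network channels.
    """
    rec = subject.recording
    if cfg.bandpass is not None:
        rec = bandpass_filter(rec, *cfg.bandpass)
    if cfg.notch is not None:
        rec = notch_filter(rec, *cfg.notch)
    if cfg.resample_to is not None and cfg.resample_to != rec.fs:
        rec = resample(rec, cfg.resample_to)
    rec = rereference_linked_ears(rec)
    epochs = {}
    for task in cfg.tasks:
        ep = baseline_correct(epoch(rec, task))
        if subject.affected_side == "right":
            ep = mirror_lateral(ep, DEFAULT_MONTAGE)
        epochs[task] = ep
    return epochs


def _metric_rows(subject, task, band, ms) -> list[dict]:
    rows = []
    for level, vals in ms.per_level.items():
        rows.append(
            {"subject_id": subject.subject_id, "group": subject.group,
             "task": task, "band": band, "sparsity": level, **vals}
        )
    rows.append(
        {"subject_id": subject.subject_id, "group": subject.group,
         "task": task, "band": band, "sparsity": "aggregate", **ms.as_dict()}
    )
    return rows


def run_pipeline(cfg: RunConfig, out_dir: str | Path, resume: bool = False) -> Path:
    """Execute every stage and write all artifacts under ``out_dir``.

    With ``resume=True``, stages whose outputs already exist are skipped
    and later stages are recomputed from the stored intermediates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conn_dir = out / "conn"
    stats_dir = out / "stats"
    conn_dir.mkdir(exist_ok=True)
    stats_dir.mkdir(exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())

    metrics_path = out / "metrics.csv"
    manifest_path = out / "cohort.csv"
    rng = np.random.default_rng(cfg.seed)
    sim_seed = int(rng.integers(2**31 - 1))
    net_seed = int(rng.integers(2**31 - 1))

    if resume and metrics_path.exists() and manifest_path.exists():
        logger.info("resuming from existing metric table %s", metrics_path)
        metrics = pd.read_csv(metrics_path)
        manifest = snio.read_manifest_csv(manifest_path)
    else:
        coupling = default_coupling(
            bands=cfg.coupling_bands,
            noise_sd=cfg.noise_sd,
            mixing_strength=cfg.mixing_strength,
        )
        cohort = generate_cohort(
            cfg.n_per_group,
            base_coupling=coupling,
            patient_attenuation=cfg.patient_attenuation,
            seed=sim_seed,
            right_affected_fraction=cfg.right_affected_fraction,
            n_trials=cfg.n_trials,
            fs=cfg.fs,
            tasks=cfg.tasks,
            gap_s=cfg.gap_s,
        )
        snio.write_manifest_csv(cohort, manifest_path)
        manifest = snio.read_manifest_csv(manifest_path)

        bands = [BAND_BY_NAME[b] for b in cfg.bands]
        profile = ThresholdProfile(levels=cfg.sparsity_levels)
        rows: list[dict] = []
        net_rng = np.random.default_rng(net_seed)
        for subject in cohort:
            epochs = preprocess_subject(subject, cfg)
            for task, ep in epochs.items():
                mats = epochs_to_band_matrices(
                    ep, bands, window_s=cfg.window_s, hop_s=cfg.hop_s,
                    per_window=cfg.per_window,
                )
                for band_name, m in mats.items():
                    snio.write_connectivity_csv(
                        m, conn_dir / f"{subject.subject_id}_{task}_{band_name}.csv"
                    )
                    ms = metrics_over_thresholds(
                        m, profile, n_realizations=cfg.n_realizations,
                        seed=int(net_rng.integers(2**31 - 1)),
                        with_sw=cfg.with_sw,
                    )
                    rows.extend(_metric_rows(subject, task, band_name, ms))
            logger.info("subject %s done", subject.subject_id)
        metrics = pd.DataFrame(rows)
        metrics.to_csv(metrics_path, index=False)

    agg = metrics[metrics["sparsity"] == "aggregate"]
    stat_metrics = [c for c in ("cc", "le", "ge", "sw") if c in agg.columns]
    long = agg.melt(
        id_vars=["subject_id", "group", "task", "band"],
        value_vars=stat_metrics, var_name="metric", value_name="value",
    ).dropna(subset=["value"])
    comparisons = compare_cohort(long, cfg.gate_alpha, cfg.fdr_scope)
    comparisons.to_csv(stats_dir / "comparisons.csv", index=False)
    correlations = correlate_mas(long, manifest, mas_col=cfg.mas_col)
    correlations.to_csv(stats_dir / "correlations.csv", index=False)

    run_manifest = {
        "config_hash": cfg.config_hash,
        "master_seed": cfg.seed,
        "stage_seeds": {"simulate": sim_seed, "network": net_seed},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": int(manifest.shape[0]),
        "n_comparisons": int(comparisons.shape[0]),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return out


def report(run_dir: str | Path) -> str:
    """Summary table of a finished run: group means +/- SD per metric/task/
    band, and the FDR-significant comparisons."""
    run_dir = Path(run_dir)
    comp = pd.read_csv(run_dir / "stats" / "comparisons.csv")
    lines = ["metric  task    band    patient (mean+/-SD)   control (mean+/-SD)   p_fdr"]
    for r in comp.itertuples():
        lines.append(
            f"{r.metric:<7} {r.task:<7} {r.band:<7} "
            f"{r.mean_a:6.3f} +/- {r.sd_a:5.3f}     "
            f"{r.mean_b:6.3f} +/- {r.sd_b:5.3f}     {r.p_fdr:.4f}"
        )
    sig = comp[comp["p_fdr"] < 0.05]
    if sig.empty:
        lines.append("no significant comparisons")
    else:
        lines.append("FDR-significant (p_fdr < 0.05):")
        for r in sig.itertuples():
            direction = "<" if r.mean_a < r.mean_b else ">"
            lines.append(
                f"  {r.metric} / {r.task} / {r.band}: patient {direction} control "
                f"({r.test}, p_fdr={r.p_fdr:.4f}, d={r.cohens_d:.2f})"
            )
    return "\n".join(lines)
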