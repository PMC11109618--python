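"""CSV session dialect, pipeline configuration, and the end-to-end run.

Sessions interchange as long-format CSV with the columns

    subject_id, label, node, t_s, acc_x, acc_y, acc_z, av_x, av_y, av_z

sorted by (subject_id, node, t_s), with a uniform 1/fs time grid and missing
samples written as empty fields.  Gzip-compressed files (``.csv.gz``) are
read and written transparently.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .classification import EvaluationReport, evaluate_pipeline
from .features import build_all_matrices
from .preprocessing import (MOVEMENT_LOWPASS, FilterSpec, clean_session,
                            filter_session, segment_cohort)
from .selection import build_hybrid
from .session import CHANNELS, PLACEMENTS, ImuSession, Label, NodePlacement
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "SESSION_COLUMNS",
    "PipelineConfig",
    "read_sessions",
    "write_sessions",
    "run_pipeline",
]

logger = logging.getLogger("gma")

SESSION_COLUMNS = ("subject_id", "label", "node", "t_s",
                   "acc_x", "acc_y", "acc_z", "av_x", "av_y", "av_z")


def write_sessions(sessions: list[ImuSession], path) -> None:
    """Serialize a cohort to the long-format CSV dialect."""
    chunks = []
    for sess in sessions:
        t = np.round(np.arange(sess.n_samples) / sess.fs, 3)
        for node in PLACEMENTS:
            arr = sess.nodes[node]
            df = pd.DataFrame({
                "subject_id": sess.subject_id,
                "label": sess.label.value,
                "node": node.value,
                "t_s": t,
            })
            for ci, ch in enumerate(CHANNELS):
                df[ch] = arr[ci]
            chunks.append(df)
    out = pd.concat(chunks, ignore_index=True)
    out.sort_values(["subject_id", "node", "t_s"], kind="stable", inplace=True)
    out.to_csv(path, index=False, float_format="%.6g")


def read_sessions(path) -> list[ImuSession]:
    """Parse the CSV dialect back into sessions (missing fields -> NaN)."""
    df = pd.read_csv(path)
    missing_cols = set(SESSION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"malformed header: missing columns {sorted(missing_cols)}")
    unknown_nodes = set(df["node"].unique()) - {p.value for p in PLACEMENTS}
    if unknown_nodes:
        rows = df.index[df["node"].isin(unknown_nodes)][:3] + 2  # 1-based + header
        raise ValueError(f"unknown node(s) {sorted(unknown_nodes)} "
                         f"(first offending file lines: {rows.tolist()})")
    df = df.sort_values(["subject_id", "node", "t_s"], kind="stable")
    sessions = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        labels = sub["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"subject {subject_id}: inconsistent labels {labels}")
        nodes = {}
        n_ref: int | None = None
        fs: float | None = None
        for node_name, nd in sub.groupby("node", sort=False):
            t = nd["t_s"].to_numpy(dtype=float)
            if len(t) < 2:
                raise ValueError(f"subject {subject_id}, node {node_name}: "
                                 "fewer than 2 samples")
            # timestamps carry 3 decimals, so dt may jitter by up to 1 ms
            dt = np.diff(t)
            dt_mean = (t[-1] - t[0]) / (len(t) - 1)
            if not np.allclose(dt, dt_mean, atol=1.5e-3):
                bad = int(np.argmax(np.abs(dt - dt_mean) > 1.5e-3))
                raise ValueError(
                    f"subject {subject_id}, node {node_name}: non-uniform "
                    f"time grid near row {bad + 1}")
            fs_node = 1.0 / dt_mean
            if fs is None:
                fs = fs_node
            elif not np.isclose(fs, fs_node, rtol=1e-3):
                raise ValueError(f"subject {subject_id}: nodes disagree on fs")
            if n_ref is None:
                n_ref = len(t)
            elif len(t) != n_ref:
                raise ValueError(f"subject {subject_id}: nodes disagree on "
                                 "channel length")
            nodes[NodePlacement(node_name)] = np.vstack(
                [nd[ch].to_numpy(dtype=float) for ch in CHANNELS])
        assert fs is not None and n_ref is not None
        # snap to an integer rate when the rounded timestamps imply one
        fs = float(round(fs)) if abs(fs - round(fs)) < 0.01 else float(fs)
        sessions.append(ImuSession(
            subject_id=str(subject_id), label=Label(labels[0]), fs=fs,
            duration_s=n_ref / fs, nodes=nodes))
    return sessions


class PipelineConfig(BaseModel):
    """Every tunable of the pipeline; defaults follow the study protocol."""

    model_config = ConfigDict(extra="forbid")

    fs: float = 30.0
    window_s: float = 120.0
    overlap_s: float = 10.0
    lowpass_hz: float = 14.0
    filter_order: int = 4
    k_top: int = 10
    alpha: float = 0.05
    smote_k: int = 5
    model: str = "LR"
    multiclass: bool = False
    split: float = 0.8
    rounds: int = 50
    folds: int = 5
    repeats: int = 1
    seed: int = 0
    smote_mode: str = "train_only"
    granularity: str = "frame"
    entropy_max_samples: int = 1024
    # generator settings (used when no input cohort is given)
    n_normal: int = 12
    n_low_risk: int = 3
    n_high_risk: int = 3
    duration_s: float = 360.0
    effect_scale: float = 2.0
    bulge_rate: float = 0.5
    missing_rate: float = 0.002
    noise_sd: float = 0.01

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.window_s <= self.overlap_s:
            raise ValueError("window_s must exceed overlap_s")
        if not (0 < self.split < 1):
            raise ValueError("split must be in (0, 1)")
        if not (0 < self.lowpass_hz < self.fs / 2):
            raise ValueError("lowpass_hz must lie in (0, Nyquist)")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_normal=self.n_normal, n_low_risk=self.n_low_risk,
            n_high_risk=self.n_high_risk, duration_s=self.duration_s,
            fs=self.fs, effect_scale=self.effect_scale,
            bulge_rate=self.bulge_rate, missing_rate=self.missing_rate,
            noise_sd=self.noise_sd, seed=self.seed)


def run_pipeline(config: PipelineConfig,
                 sessions: list[ImuSession] | None = None,
                 out_dir=None) -> EvaluationReport:
    """Execute clean -> filter -> segment -> fuse -> features -> rank/select
    -> hybrid -> balance -> evaluate, logging per-stage counts.

    When ``sessions`` is None a synthetic cohort is generated from the
    config.  When ``out_dir`` is given, feature reports, the selection
    table, metrics, the confusion matrix and a reproducibility manifest are
    written there.
    """
    if sessions is None:
        sessions = generate_cohort(config.cohort_spec())
        logger.info("generated %d synthetic sessions", len(sessions))

    cleaned = [clean_session(s) for s in sessions]
    lp = FilterSpec(kind="lowpass", f_high=config.lowpass_hz,
                    order=config.filter_order)
    filtered = [filter_session(s, lp) for s in cleaned]
    logger.info("cleaned and low-pass filtered %d sessions at %.1f Hz",
                len(filtered), config.lowpass_hz)

    frames = segment_cohort(filtered, window_s=config.window_s,
                            overlap_s=config.overlap_s)
    if len(frames) == 0:
        raise RuntimeError("segmentation produced no frames; sessions are "
                           "shorter than one window")
    binary = [lab.binary for lab in frames.labels]
    logger.info("segmented into %d frames (%d Normal / %d Risky)",
                len(frames), binary.count("Normal"), binary.count("Risky"))

    matrices = build_all_matrices(
        frames, entropy_max_samples=config.entropy_max_samples)
    logger.info("built %d feature matrices: %s", len(matrices),
                ", ".join(f"{m.name} {m.shape[0]}x{m.shape[1]}"
                          for m in matrices))

    y_sel = matrices[0].binary_labels
    hybrid = build_hybrid(matrices, y_sel, k=config.k_top, alpha=config.alpha)
    logger.info("hybrid matrix: %d x %d (per source: %s)",
                hybrid.shape[0], hybrid.shape[1], hybrid.per_source_counts)

    report = evaluate_pipeline(
        matrices, config.model, multiclass=config.multiclass,
        split=config.split, rounds=config.rounds, folds=config.folds,
        repeats=config.repeats, seed=config.seed,
        smote_mode=config.smote_mode, granularity=config.granularity,
        k=config.k_top, alpha=config.alpha, smote_k=config.smote_k)
    logger.info("%s mean accuracy %.3f +/- %.3f over %d rounds",
                config.model, report.mean_accuracy, report.sd["accuracy"],
                len(report.round_metrics))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hybrid.report().to_csv(out / "selected_features.csv", index=False)
        report.to_json(out / "metrics.json")
        report.confusion.to_dataframe().to_csv(out / "confusion.csv")
        for m in matrices:
            m.to_csv(out / f"features_{m.name}.csv")
        manifest = {
            "package_version": __version__,
            "python": sys.version.split()[0],
            "config": config.model_dump(),
            "n_sessions": len(sessions),
            "n_frames": len(frames),
            "frame_labels": {"Normal": binary.count("Normal"),
                             "Risky": binary.count("Risky")},
            "hybrid_shape": list(hybrid.shape),
            "hybrid_per_source": hybrid.per_source_counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report
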