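"""Plain-text readers/writers and the structured experiment configuration."""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml

from .evaluation import ConfusionMatrix, MetricsReport
from .models import ModelConfig
from .preprocessing import PreprocessConfig
from .synthetic import BONN_RATE, SimulationConfig
from .training import TrainConfig, TrainingHistory
from .types import GROUPS, HEALTHY, RawRecording, SegmentSet

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed file contents."""


class MetadataError(ValueError):
    """Missing or invalid sidecar/header metadata."""


# ---------------------------------------------------------------------------
# single-channel one-sample-per-line records
# ---------------------------------------------------------------------------

def read_bonn_txt(
    path: PathLike, group: str = HEALTHY, subject_id: Optional[str] = None
) -> RawRecording:
    """Read a single-channel ASCII record (one numeric sample per line) at 173.61 Hz."""
    path = Path(path)
    samples: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {line!r} on line {lineno}"
                ) from None
    if not samples:
        raise FormatError(f"{path}: file contains no samples")
    return RawRecording(
        subject_id=subject_id or path.stem,
        group=group,
        rate=BONN_RATE,
        channels=["ch1"],
        signal=np.asarray(samples)[None, :],
    )


def write_bonn_txt(rec: RawRecording, path: PathLike) -> None:
    """Write the first channel as one rounded-integer sample per line."""
    np.savetxt(path, np.round(rec.signal[0]).astype(int), fmt="%d")


# ---------------------------------------------------------------------------
# multichannel tabular text (header metadata + channel-name row + sample rows)
# ---------------------------------------------------------------------------

def write_multichannel(rec: RawRecording, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# group: {rec.group}\n")
        fh.write(f"# rate: {rec.rate!r}\n")
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.signal.T, fmt="%.10g", delimiter="\t")


def read_multichannel(path: PathLike) -> RawRecording:
    """Read a tabular-text recording; rate metadata is mandatory."""
    path = Path(path)
    meta: Dict[str, str] = {}
    channels: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not channels:
                channels = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(channels):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(channels)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                raise FormatError(f"{path}: non-numeric value on line {lineno}") from None
    if "rate" not in meta:
        raise MetadataError(f"{path}: missing required 'rate' metadata")
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    group = meta.get("group", HEALTHY)
    if group not in GROUPS:
        raise MetadataError(f"{path}: unknown group {group!r}")
    return RawRecording(
        subject_id=meta.get("subject_id", path.stem),
        group=group,
        rate=float(meta["rate"]),
        channels=channels,
        signal=np.asarray(rows).T,
    )


def write_cohort(recordings: Sequence[RawRecording], out_dir: PathLike) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("subject_id\tgroup\trate\tfile\n")
        for rec in recordings:
            fname = f"{rec.subject_id}.tsv"
            write_multichannel(rec, out_dir / fname)
            fh.write(f"{rec.subject_id}\t{rec.group}\t{rec.rate!r}\t{fname}\n")


def read_cohort(in_dir: PathLike) -> List[RawRecording]:
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {in_dir}")
    recordings = []
    with open(manifest) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fcol = header.index("file")
        for line in fh:
            if line.strip():
                recordings.append(read_multichannel(in_dir / line.rstrip("\n").split("\t")[fcol]))
    return recordings


# ---------------------------------------------------------------------------
# segment sets
# ---------------------------------------------------------------------------

def write_segments(segments: SegmentSet, out_dir: PathLike) -> None:
    """Matrix container (one flattened segment per row) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, _, subs = segments.to_arrays()
    n, c, w = X.shape
    np.savetxt(out_dir / "segments.tsv", X.reshape(n, c * w), fmt="%.10g", delimiter="\t")
    with open(out_dir / "segments_manifest.tsv", "w") as fh:
        fh.write("index\tsubject_id\tlabel\tn_channels\tn_samples\n")
        for i, seg in enumerate(segments):
            fh.write(f"{i}\t{seg.subject_id}\t{seg.label}\t{c}\t{w}\n")


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalSettings:
    k_folds: int = 5
    test_frac: float = 0.3
    val_frac: float = 0.2


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment from a master seed."""

    simulation: SimulationConfig = SimulationConfig()
    preprocessing: PreprocessConfig = PreprocessConfig()
    model: ModelConfig = ModelConfig()
    training: TrainConfig = TrainConfig()
    evaluation: EvalSettings = EvalSettings()
    n_healthy: int = 21
    n_ep: int = 14
    model_kind: str = "tcnsa"
    output_dir: Optional[str] = None
    seed: int = 0


_SECTIONS = {
    "simulation": SimulationConfig,
    "preprocessing": PreprocessConfig,
    "model": ModelConfig,
    "training": TrainConfig,
    "evaluation": EvalSettings,
}


def _coerce_section(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise MetadataError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    # YAML gives lists where the dataclasses expect tuples
    clean = {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**clean)


def experiment_config_from_dict(raw: dict) -> ExperimentConfig:
    kwargs = {}
    for section, cls in _SECTIONS.items():
        kwargs[section] = _coerce_section(cls, raw.get(section, {}) or {})
    for scalar in ("n_healthy", "n_ep", "model_kind", "output_dir", "seed"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return ExperimentConfig(**kwargs)


def load_experiment_config(path: PathLike) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return experiment_config_from_dict(raw)


def save_experiment_config(cfg: ExperimentConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

def write_history(history: TrainingHistory, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\ttrain_acc\tval_acc\n")
        for row in zip(history.epoch, history.train_loss, history.val_loss,
                       history.train_acc, history.val_acc):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def write_confusion(cm: ConfusionMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\tpred_healthy\tpred_EP\n")
        fh.write(f"true_healthy\t{cm.tn}\t{cm.fp}\n")
        fh.write(f"true_EP\t{cm.fn}\t{cm.tp}\n")


def write_metrics_report(report: MetricsReport, out_dir: PathLike) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "model_kind": report.model_kind,
        "per_fold": report.per_fold,
        "mean": report.mean,
        "std": report.std,
        "auc_mean": report.averaged_roc.auc_mean if report.averaged_roc else None,
        "auc_std": report.averaged_roc.auc_std if report.averaged_roc else None,
        "threshold_counts": report.threshold_counts,
        "per_participant": report.per_participant,
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(out_dir / "metrics_per_fold.tsv", "w") as fh:
        names = list(report.per_fold[0]) if report.per_fold else []
        fh.write("fold\t" + "\t".join(names) + "\n")
        for i, fold in enumerate(report.per_fold):
            fh.write(f"{i}\t" + "\t".join(f"{fold[m]:.6g}" for m in names) + "\n")
    if report.averaged_roc is not None:
        roc = report.averaged_roc
        with open(out_dir / "roc_mean.tsv", "w") as fh:
            fh.write("fpr\tmean_tpr\tstd_tpr\n")
            for f, m, s in zip(roc.fpr_grid, roc.mean_tpr, roc.std_tpr):
                fh.write(f"{f:.6g}\t{m:.6g}\t{s:.6g}\n")
    for i, cm in enumerate(report.confusions):
        write_confusion(cm, out_dir / f"confusion_fold{i}.tsv")
    with open(out_dir / "per_participant.tsv", "w") as fh:
        fh.write("subject_id\taccuracy\n")
        for sid, acc in sorted(report.per_participant.items()):
            fh.write(f"{sid}\t{acc:.6g}\n")
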