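"""End-to-end run orchestration with config, provenance and artifacts.

``run_pipeline`` executes simulate -> segment -> detect/filter ->
normalize -> cross-validated training -> metrics -> grad-CAM and writes
everything (per-fold metric CSVs, confusion matrices, training curves,
grad-CAM overlays, a JSON summary) under one output directory.  Every
output carries the config hash, the seed and the package version, so a
results directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .interpret import grad_cam, overlay_plot
from .io_ecg import SegmentSet
from .model import NYHAClassifier
from .preprocess import (
    RPeakParams,
    filter_segments,
    segment_record,
    valid_durations,
    zscore_set,
)
from .synthetic import SynthConfig, synth_dataset
from .train_eval import train_cv

logger = logging.getLogger("nyhagrade")

__all__ = ["RunConfig", "run_pipeline", "config_hash"]


@dataclass
class SynthSection:
    n_records_per_class: tuple = (10, 10, 10, 10)
    record_seconds: int = 240
    fs: float = 125.0
    noise_sd: float = 0.02
    null_effect: bool = False


@dataclass
class PreprocessSection:
    duration_s: int = 12
    min_peaks: int = 2
    allow_uneven: bool = False
    window_s: float = 1.5
    threshold_k: float = 1.0
    refractory_s: float = 0.2
    prominence_frac: float = 0.5
    max_qrs_width_s: float = 0.16


@dataclass
class ModelSection:
    variant: str = "cnn_lstm_se"
    conv_filters: tuple = (8, 16, 32)
    kernel_sizes: tuple = (7, 5, 3)
    pool_size: int = 5
    n_lstm_layers: int = 2
    lstm_hidden: int = 24
    se_reduction: int = 8
    dropout_scheme: str = "B"


@dataclass
class TrainSection:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.001
    folds: int = 5
    class_weighting: str = "inverse_frequency"
    split: str = "segment"  # or "patient"


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {"synth": SynthSection, "preprocess": PreprocessSection,
                    "model": ModelSection, "train": TrainSection}
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                sec_cls = sections[key]
                known = {f.name for f in dataclasses.fields(sec_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown key(s) in [{key}]: {sorted(unknown)}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = sec_cls(**value)
            elif key in {"out_dir", "seed", "log_level"}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(_listify(cfg.to_dict()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _rpeak_params(pp: PreprocessSection) -> RPeakParams:
    return RPeakParams(
        window_s=pp.window_s, threshold_k=pp.threshold_k,
        refractory_s=pp.refractory_s, prominence_frac=pp.prominence_frac,
        max_qrs_width_s=pp.max_qrs_width_s,
    )


def check_duration(duration_s: int, record_seconds: int, allow_uneven: bool = False) -> None:
    """Enforce the even-division rule at the pipeline boundary."""
    allowed = valid_durations(record_seconds, 2, min(20, record_seconds))
    if duration_s not in allowed and not allow_uneven:
        raise ValueError(
            f"duration {duration_s}s does not divide {record_seconds}s records evenly "
            f"(usable 2-20 s durations: {allowed}); durations that cannot evenly "
            "segment the record are excluded"
        )


def run_pipeline(cfg: RunConfig, records=None) -> Path:
    """Execute the full workflow; returns the output directory.

    ``records`` may carry pre-loaded :class:`~nyhagrade.io_ecg.ECGRecord`
    objects (e.g. real WFDB data); by default the synthetic cohort in
    ``cfg.synth`` is generated.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    chash = config_hash(cfg)
    logger.info("run config hash %s seed %d", chash, cfg.seed)
    cfg.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        if records is None:
            synth_cls = SynthConfig.null_effect if cfg.synth.null_effect else SynthConfig
            scfg = synth_cls(
                fs=cfg.synth.fs,
                record_seconds=cfg.synth.record_seconds,
                n_records_per_class=tuple(cfg.synth.n_records_per_class),
                noise_sd=cfg.synth.noise_sd,
                seed=cfg.seed,
            )
            records, _, manifest = synth_dataset(scfg)
            manifest.to_csv(out / "records_manifest.csv", index=False)

        stage = "segment"
        check_duration(cfg.preprocess.duration_s, cfg.synth.record_seconds,
                       cfg.preprocess.allow_uneven)
        all_segments = []
        for rec in records:
            all_segments.extend(segment_record(rec, cfg.preprocess.duration_s).segments)
        seg_set = SegmentSet(all_segments, duration_s=cfg.preprocess.duration_s,
                             fs=records[0].fs)
        n_pre = len(seg_set)

        stage = "filter"
        retained, dropped = filter_segments(
            seg_set, min_peaks=cfg.preprocess.min_peaks,
            params=_rpeak_params(cfg.preprocess),
        )
        logger.info("segments: %d before filtering, %d retained, %d dropped",
                    n_pre, len(retained), dropped)

        stage = "normalize"
        X, y = zscore_set(retained)
        groups = np.array([s.subject_id for s in retained.segments])

        stage = "train"
        est = NYHAClassifier(
            variant=cfg.model.variant,
            conv_filters=tuple(cfg.model.conv_filters),
            kernel_sizes=tuple(cfg.model.kernel_sizes),
            pool_size=cfg.model.pool_size,
            n_lstm_layers=cfg.model.n_lstm_layers,
            lstm_hidden=cfg.model.lstm_hidden,
            se_reduction=cfg.model.se_reduction,
            dropout_scheme=cfg.model.dropout_scheme,
            epochs=cfg.train.epochs,
            batch_size=cfg.train.batch_size,
            learning_rate=cfg.train.learning_rate,
            class_weighting=cfg.train.class_weighting,
            seed=cfg.seed,
        )
        result = train_cv(
            X, y, estimator=est, k=cfg.train.folds, seed=cfg.seed,
            groups=groups if cfg.train.split == "patient" else None,
        )

        stage = "report"
        rows = []
        for i, fold in enumerate(result.folds, start=1):
            np.savetxt(out / f"confusion_fold{i}.csv", fold.confusion.counts,
                       fmt="%d", delimiter=",")
            for c, metrics in fold.report.per_class.items():
                rows.append({"fold": i, "class": int(c), **metrics})
            rows.append({"fold": i, "class": "macro", **fold.report.macro,
                         "overall_acc": fold.report.overall_accuracy})
            if fold.history:
                pd.DataFrame(fold.history).to_csv(out / f"curves_fold{i}.csv",
                                                  index=False)
            fold.model.save(out / f"model_fold{i}.npz")
        rows.append({"fold": "mean", "class": "macro", **result.averaged.macro,
                     "overall_acc": result.averaged.overall_accuracy})
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)

        stage = "gradcam"
        model0 = result.folds[0].model
        for c in model0.classes_:
            idx = np.flatnonzero(y == c)
            if idx.size == 0:
                continue
            cam = grad_cam(model0, X[idx[0]], int(c))
            overlay_plot(X[idx[0]], cam, out / f"gradcam_class{int(c)}.png")

        summary = {
            "config_hash": chash,
            "seed": cfg.seed,
            "version": __version__,
            "n_segments_before_filter": n_pre,
            "n_segments_after_filter": len(retained),
            "n_dropped": dropped,
            "overall_accuracy_mean": result.averaged.overall_accuracy,
            "macro": result.averaged.macro,
            "fold_overall_accuracy": [f.report.overall_accuracy for f in result.folds],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
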