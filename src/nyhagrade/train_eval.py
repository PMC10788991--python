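"""Cross-validated training and evaluation under class imbalance.

Evaluation follows the four-metric convention for multi-class ECG
classification: each class is reduced one-vs-rest to TP/FP/TN/FN and

    Acc = (TP + TN) / (TP + TN + FP + FN)
    PPV = TP / (TP + FP)
    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)

all in percent.  Macro values are unweighted means over classes (a
weighted variant is available); a class with an empty denominator is
reported as missing and excluded from the macro with a warning.  The
report also carries the overall multi-class accuracy (trace / total),
which is what a single headline "Acc" number refers to.

Folds are stratified (per-fold class proportions within one item of the
global proportions).  Splitting is segment-level by default, mirroring
common practice for fixed-duration ECG segments; patient-level
(group-aware) splitting is available and recommended when subject leakage
matters — segments of one patient then never span the train/test divide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .model import NYHAClassifier

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_kfold",
    "class_weights",
    "compute_metrics",
    "train_cv",
    "CVResult",
]

METRIC_NAMES = ("acc", "ppv", "sen", "spe")


@dataclass
class TrainConfig:
    """Training settings: Adam, lr 0.001, 60 epochs, batch 32, 5 folds."""

    learning_rate: float = 0.001
    epochs: int = 60
    batch_size: int = 32
    folds: int = 5
    class_weighting: str = "inverse_frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


def stratified_kfold(
    labels: Sequence, k: int, seed: int = 0, groups: Optional[Sequence] = None
) -> list[np.ndarray]:
    """k disjoint stratified test index sets covering all indices exactly once.

    With ``groups`` (e.g. subject ids) the split is additionally
    group-aware, so no group straddles folds.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        offender = small[0].item() if isinstance(small[0], np.generic) else small[0]
        raise ValueError(
            f"class {offender} has only {int(counts[classes == small[0]][0])} "
            f"member(s); need at least k={k} per class"
        )
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels, groups)]


def class_weights(labels: Sequence) -> dict:
    """Inverse-frequency class weights, w_c = N / (K * n_c).

    Balanced labels give every class weight 1; rarer classes get
    proportionally larger weights (the 'balanced' convention).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes, got only {classes.tolist()}")
    n, k = len(labels), len(classes)
    return {c: n / (k * nc) for c, nc in zip(classes, counts.astype(float))}


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, np.asarray(y_pred)]))
        return cls(
            counts=sk_confusion_matrix(y_true, y_pred, labels=list(classes)),
            classes=tuple(classes),
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against all others."""
        tp = int(self.counts[class_index, class_index])
        fn = int(self.counts[class_index].sum() - tp)
        fp = int(self.counts[:, class_index].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, tn, fn


@dataclass
class MetricsReport:
    """Per-class and averaged Acc/PPV/Sen/Spe in percent.

    ``per_class[c][m]`` may be ``None`` when the metric's denominator is
    empty for class ``c``; such entries are excluded from the macro mean.
    ``overall_accuracy`` is trace/total of the multi-class matrix.
    """

    per_class: dict
    macro: dict
    weighted: dict
    overall_accuracy: float
    support: dict = field(default_factory=dict)

    @classmethod
    def average(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Arithmetic mean over fold reports (missing entries propagate)."""

        def mean(values):
            vals = [v for v in values if v is not None]
            return float(np.mean(vals)) if vals else None

        classes = list(reports[0].per_class)
        per_class = {
            c: {m: mean([r.per_class[c][m] for r in reports]) for m in METRIC_NAMES}
            for c in classes
        }
        macro = {m: mean([r.macro[m] for r in reports]) for m in METRIC_NAMES}
        weighted = {m: mean([r.weighted[m] for r in reports]) for m in METRIC_NAMES}
        return cls(
            per_class=per_class,
            macro=macro,
            weighted=weighted,
            overall_accuracy=float(np.mean([r.overall_accuracy for r in reports])),
            support={c: int(np.sum([r.support.get(c, 0) for r in reports]))
                     for c in classes},
        )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest Acc/PPV/Sen/Spe per class, macro/weighted means, overall Acc."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict = {}
    support: dict = {}
    for i, c in enumerate(cm.classes):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        entry = {"acc": 100.0 * (tp + tn) / cm.total}
        if tp + fp == 0:
            warnings.warn(
                f"class {c}: no predicted positives; PPV undefined and excluded "
                "from the macro average", stacklevel=2,
            )
            entry["ppv"] = None
        else:
            entry["ppv"] = 100.0 * tp / (tp + fp)
        entry["sen"] = 100.0 * tp / (tp + fn) if tp + fn else None
        entry["spe"] = 100.0 * tn / (tn + fp) if tn + fp else None
        per_class[c] = entry
        support[c] = tp + fn

    def agg(metric, weights=None):
        pairs = [(per_class[c][metric], 1.0 if weights is None else weights[c])
                 for c in cm.classes if per_class[c][metric] is not None]
        if not pairs:
            return None
        v, w = zip(*pairs)
        return float(np.average(v, weights=w))

    macro = {m: agg(m) for m in METRIC_NAMES}
    weighted = {m: agg(m, weights=support) for m in METRIC_NAMES}
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        overall_accuracy=100.0 * np.trace(cm.counts) / cm.total,
        support=support,
    )


@dataclass
class FoldResult:
    model: object
    confusion: ConfusionMatrix
    report: MetricsReport
    test_indices: np.ndarray
    history: Optional[dict] = None


@dataclass
class CVResult:
    folds: list
    averaged: MetricsReport

    @property
    def fold_reports(self) -> list:
        return [f.report for f in self.folds]


def train_cv(
    X,
    y,
    estimator=None,
    k: int = 5,
    seed: int = 0,
    groups: Optional[Sequence] = None,
    log_curves: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of a classifier.

    Each fold trains a fresh clone on 4/5 of the data and evaluates on the
    held-out 1/5; the averaged report is the arithmetic mean of the fold
    reports.  ``estimator`` is any sklearn-style classifier (default: a
    :class:`~nyhagrade.model.NYHAClassifier`); pass ``groups`` for
    patient-level splitting.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if estimator is None:
        estimator = NYHAClassifier(seed=seed)
    test_sets = stratified_kfold(y, k=k, seed=seed, groups=groups)
    classes = tuple(np.unique(y))
    folds = []
    for fold_idx, test_idx in enumerate(test_sets):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = clone(estimator)
        if hasattr(model, "seed"):
            model.set_params(seed=seed + 101 * fold_idx)
        fit_kwargs = {}
        if log_curves and isinstance(model, NYHAClassifier):
            fit_kwargs["validation_data"] = (X[test_idx], y[test_idx])
        model.fit(X[train_mask], y[train_mask], **fit_kwargs)
        y_pred = model.predict(X[test_idx])
        cm = ConfusionMatrix.from_predictions(y[test_idx], y_pred, classes=classes)
        folds.append(
            FoldResult(
                model=model,
                confusion=cm,
                report=compute_metrics(cm),
                test_indices=np.asarray(test_idx),
                history=getattr(model, "history_", None),
            )
        )
    averaged = MetricsReport.average([f.report for f in folds])
    return CVResult(folds=folds, averaged=averaged)
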