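"""Five-fold cross-validated training/evaluation and the four report metrics.

Metrics derive from the confusion matrix.  For binary tasks the seizure
class (highest class index) is the positive class, and

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

For multi-class tasks, accuracy is the overall fraction correct
(trace / total, the direct extension of the binary formula) while
specificity, sensitivity and F1 are unweighted one-vs-rest macro averages.
All metrics are reported in percent.
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .architecture import (
    ModelConfig,
    TrainConfig,
    ablate,
    build_model,
    get_config,
)
from .nn import TrainingDivergedError
from .preprocess import SegmentedDataset, build_study_dataset
from .records import RecordValidationError, TaskSpec, load_sets, make_task
from .synthetic import generate_dataset


class MetricSet(NamedTuple):
    """The four report metrics, in percent."""

    accuracy: float
    specificity: float
    sensitivity: float
    f1: float


@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_order: tuple[int, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts.ndim != 2
                or self.counts.shape[0] != self.counts.shape[1]):
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_order:
            self.class_order = tuple(range(self.counts.shape[0]))

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
        return cls(counts=counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; metric set to 0",
                      stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """One-vs-rest sensitivity/specificity/F1 per class (fractions)."""
    counts = cm.counts
    k = cm.n_classes
    total = counts.sum()
    sens, spec, f1 = np.zeros(k), np.zeros(k), np.zeros(k)
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = _safe_ratio(tp, tp + fn, f"sensitivity of class {c}")
        spec[c] = _safe_ratio(tn, tn + fp, f"specificity of class {c}")
        f1[c] = _safe_ratio(2 * tp, 2 * tp + fp + fn, f"F1 of class {c}")
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Compute the four metrics (percent) from a confusion matrix."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = _safe_ratio(np.trace(counts), total, "accuracy")
    if cm.n_classes == 2:
        # positive class = highest index (the seizure class)
        tp, fn = counts[1, 1], counts[1, 0]
        tn, fp = counts[0, 0], counts[0, 1]
        sens = _safe_ratio(tp, tp + fn, "sensitivity")
        spec = _safe_ratio(tn, tn + fp, "specificity")
        f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1")
    else:
        per_class = per_class_metrics(cm)
        sens = per_class["sensitivity"].mean()
        spec = per_class["specificity"].mean()
        f1 = per_class["f1"].mean()
    return MetricSet(accuracy=100.0 * accuracy, specificity=100.0 * spec,
                     sensitivity=100.0 * sens, f1=100.0 * f1)


def make_folds(dataset: SegmentedDataset, folds: int = 5, seed: int = 0,
               group_aware: bool = False
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of the segment indices.

    Folds are disjoint and exhaustive; per-class fold sizes differ by at
    most one.  ``group_aware=True`` additionally keeps all segments of one
    source record in the same fold (leakage-free, but per-fold sizes then
    deviate from the plain segment-level arithmetic).
    """
    if folds < 2:
        raise RecordValidationError("folds must be >= 2")
    counts = dataset.class_counts()
    if (counts < folds).any():
        lacking = [int(c) for c in np.flatnonzero(counts < folds)]
        raise RecordValidationError(
            f"classes {lacking} have fewer segments than folds={folds}")
    if group_aware:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=seed)
        split = splitter.split(dataset.segments, dataset.labels,
                               groups=dataset.group_ids)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split = splitter.split(dataset.segments, dataset.labels)
    return [(train.copy(), test.copy()) for train, test in split]


@dataclass
class MetricsReport:
    """Per-fold and fold-averaged results of one cross-validated run."""

    per_fold: list[MetricSet]
    confusions: list[ConfusionMatrix]
    train_seconds: list[float]
    infer_seconds: list[float]
    failed_folds: list[int] = field(default_factory=list)
    study: int | None = None
    task: str | None = None
    rnn_type: str | None = None
    ablation: str | None = None
    n_segments: int = 0
    fold_sizes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mean(self) -> MetricSet:
        if not self.per_fold:
            raise ValueError("no successful folds to average")
        arr = np.array(self.per_fold)
        return MetricSet(*arr.mean(axis=0))

    @property
    def complete(self) -> bool:
        return not self.failed_folds

    def to_frame(self) -> pd.DataFrame:
        """One row per fold plus a mean row."""
        rows = []
        for i, m in enumerate(self.per_fold):
            rows.append({
                "study": self.study, "task": self.task, "rnn": self.rnn_type,
                "ablation": self.ablation or "none", "fold": i,
                "accuracy": m.accuracy, "specificity": m.specificity,
                "sensitivity": m.sensitivity, "f1": m.f1,
                "train_s": self.train_seconds[i],
                "infer_s": self.infer_seconds[i],
            })
        m = self.mean
        rows.append({
            "study": self.study, "task": self.task, "rnn": self.rnn_type,
            "ablation": self.ablation or "none", "fold": "mean",
            "accuracy": m.accuracy, "specificity": m.specificity,
            "sensitivity": m.sensitivity, "f1": m.f1,
            "train_s": float(np.mean(self.train_seconds)),
            "infer_s": float(np.mean(self.infer_seconds)),
        })
        return pd.DataFrame(rows)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[labels]


def crossvalidate(dataset: SegmentedDataset, model_config: ModelConfig,
                  train_config: TrainConfig, group_aware: bool = False,
                  verbose: bool = False) -> MetricsReport:
    """Train and evaluate one configuration with stratified k-fold CV.

    Each fold trains a freshly initialized model (softmax cross-entropy,
    Adam) and is scored on its held-out segments by argmax prediction.
    Folds whose training diverges are excluded from the averages and listed
    in ``failed_folds``.
    """
    if dataset.n_classes != model_config.n_classes:
        raise RecordValidationError(
            f"dataset has {dataset.n_classes} classes but the model expects "
            f"{model_config.n_classes}")
    folds = make_folds(dataset, train_config.folds, train_config.seed,
                       group_aware=group_aware)
    x = dataset.segments[:, :, None].astype(np.float32)
    y = _one_hot(dataset.labels, dataset.n_classes)
    # independent, reproducible streams per fold
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(train_config.seed).spawn(
                      len(folds))]
    report = MetricsReport(per_fold=[], confusions=[], train_seconds=[],
                           infer_seconds=[], study=model_config.study,
                           task=model_config.task,
                           rnn_type=model_config.rnn_type,
                           n_segments=len(dataset),
                           fold_sizes=[(len(tr), len(te))
                                       for tr, te in folds])
    for i, (train_idx, test_idx) in enumerate(folds):
        model = build_model(model_config, dataset.seg_len, seed=fold_seeds[i])
        rng = np.random.default_rng(fold_seeds[i] + 1)
        t0 = time.perf_counter()
        try:
            model.fit(x[train_idx], y[train_idx], train_config.epochs,
                      train_config.batch_size, rng,
                      lr=train_config.learning_rate, verbose=verbose)
        except TrainingDivergedError as exc:
            warnings.warn(f"fold {i} failed: {exc}; excluded from averages",
                          stacklevel=2)
            report.failed_folds.append(i)
            continue
        train_s = time.perf_counter() - t0
        t0 = time.perf_counter()
        pred = model.predict(x[test_idx], train_config.batch_size)
        infer_s = time.perf_counter() - t0
        cm = ConfusionMatrix.from_predictions(dataset.labels[test_idx], pred,
                                              dataset.n_classes)
        report.per_fold.append(metrics_from_confusion(cm))
        report.confusions.append(cm)
        report.train_seconds.append(train_s)
        report.infer_seconds.append(infer_s)
        if verbose:
            m = report.per_fold[-1]
            print(f"fold {i}: accuracy {m.accuracy:.2f}% "
                  f"(train {train_s:.1f}s)")
    return report


def _load_records(data_source, seed: int, n_per_class: int = 100,
                  n_points: int = 4097):
    """Resolve a data source: 'synthetic' or a Bonn-layout directory."""
    if isinstance(data_source, str) and data_source.lower() == "synthetic":
        return generate_dataset(n_per_class=n_per_class, n_points=n_points,
                                seed=seed)
    if isinstance(data_source, (list, tuple)):
        return list(data_source)
    return load_sets(data_source)


def run_study(study: int, task: str, rnn_type: str = "lstm",
              data_source="synthetic", seed: int = 0,
              n_per_class: int = 100, epochs: int | None = None,
              group_aware: bool = False, verbose: bool = False,
              overrides: dict | None = None) -> MetricsReport:
    """End-to-end pipeline: data -> study dataset -> config -> CV report.

    ``data_source`` is a Bonn-layout directory, a pre-loaded record list, or
    ``'synthetic'`` (surrogate records seeded by ``seed``).  ``epochs``
    overrides the published epoch count (useful for quick runs).
    """
    model_config, train_config = get_config(study, task, rnn_type, seed=seed,
                                            overrides=overrides)
    if epochs is not None:
        train_config = TrainConfig(epochs=epochs,
                                   batch_size=train_config.batch_size,
                                   learning_rate=train_config.learning_rate,
                                   folds=train_config.folds, seed=seed)
    records = _load_records(data_source, seed, n_per_class=n_per_class)
    task_spec, labelled = make_task(records, task)
    dataset = build_study_dataset(labelled, study, task_spec)
    return crossvalidate(dataset, model_config, train_config,
                         group_aware=group_aware, verbose=verbose)


def run_ablation(study: int, task: str, drop: str, rnn_type: str = "lstm",
                 data_source="synthetic", seed: int = 0,
                 n_per_class: int = 100, epochs: int | None = None,
                 group_aware: bool = False,
                 verbose: bool = False) -> MetricsReport:
    """As :func:`run_study` with every conv or Bi-RNN stage removed."""
    model_config, train_config = get_config(study, task, rnn_type, seed=seed)
    model_config = ablate(model_config, drop)
    if epochs is not None:
        train_config = TrainConfig(epochs=epochs,
                                   batch_size=train_config.batch_size,
                                   learning_rate=train_config.learning_rate,
                                   folds=train_config.folds, seed=seed)
    records = _load_records(data_source, seed, n_per_class=n_per_class)
    task_spec, labelled = make_task(records, task)
    dataset = build_study_dataset(labelled, study, task_spec)
    report = crossvalidate(dataset, model_config, train_config,
                           group_aware=group_aware, verbose=verbose)
    report.ablation = drop
    return report
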