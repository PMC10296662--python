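"""Cross-validated evaluation: metrics, confusion analysis, method comparison,
and the window-duration sweep.

Precision and recall are macro-averaged: per-class one-vs-rest values
averaged with equal class weight; a class never predicted contributes
precision 0.  k-fold metrics are computed on the pooled test predictions of
all folds (per-fold metrics are also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from myogrip.classify import (
    LabeledDataset,
    TrainingConfig,
    build_model,
    predict_batch,
    predict_proba,
    train,
)
from myogrip.dataio import AnalysisWindow, Recording, segment
from myogrip.features import extract

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "confusion_and_metrics",
    "kfold_cv",
    "stratified_folds",
    "window_sweep",
    "compare_feature_methods",
    "featurize_windows",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings shared by evaluation entry points."""

    feature_method: str = "rms"
    envelope_ms: float = 50.0
    subwindow_ms: float = 500.0
    window_duration: float = 2.0
    hidden_widths: tuple[int, int] = (32, 16)
    training: TrainingConfig = field(default_factory=TrainingConfig)


@dataclass
class EvaluationReport:
    """Aggregate metrics plus the class-by-class confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    loss: float
    confusion: np.ndarray  # rows = true class, cols = predicted class
    classes: list[int]
    per_fold: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def per_class_recall(self) -> dict[int, float]:
        totals = self.confusion.sum(axis=1)
        out = {}
        for i, cls in enumerate(self.classes):
            out[cls] = float(self.confusion[i, i] / totals[i]) if totals[i] else 0.0
        return out

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in self.classes],
            columns=[f"pred_{c}" for c in self.classes],
        )


def confusion_and_metrics(
    y_true, y_pred, classes: list[int] | None = None, loss: float = float("nan")
) -> EvaluationReport:
    """Confusion matrix, accuracy, and macro precision/recall for label lists."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lists must have equal length")
    if classes is None:
        classes = sorted(set(y_true.tolist()))
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    total = conf.sum()
    accuracy = float(np.trace(conf) / total) if total else 0.0
    precisions, recalls = [], []
    for i in range(k):
        tp = conf[i, i]
        pred_i = conf[:, i].sum()
        true_i = conf[i, :].sum()
        precisions.append(tp / pred_i if pred_i else 0.0)
        recalls.append(tp / true_i if true_i else 0.0)
    return EvaluationReport(
        accuracy=accuracy,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        loss=loss,
        confusion=conf,
        classes=list(classes),
    )


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; returns a fold index per sample.

    Within each class, samples are shuffled and dealt round-robin across the
    k folds, so per-fold class counts differ by at most one.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in sorted(set(y.tolist())):
        idx = np.where(y == cls)[0]
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples, fewer than k={k}")
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def featurize_windows(windows: list[AnalysisWindow], pipeline: PipelineConfig) -> LabeledDataset:
    fvs = [
        extract(
            w,
            method=pipeline.feature_method,
            envelope_ms=pipeline.envelope_ms,
            subwindow_ms=pipeline.subwindow_ms,
        )
        for w in windows
    ]
    return LabeledDataset.from_feature_vectors(fvs)


def _mean_crossentropy(proba: np.ndarray, y: np.ndarray, classes: list[int]) -> float:
    eps = 1e-12
    idx = np.array([classes.index(int(lab)) for lab in y])
    return float(-np.mean(np.log(np.clip(proba[np.arange(len(y)), idx], eps, None))))


def kfold_cv(
    dataset: LabeledDataset | list[AnalysisWindow],
    k: int = 10,
    pipeline: PipelineConfig | None = None,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with a fresh model per fold.

    Fold assignment is at the window level (one deposited file = one task
    window).  Each fold trains a new model seeded ``seed + fold`` on the
    fold's training windows and predicts its test windows; metrics are
    computed on the pooled predictions, with per-fold metrics kept alongside.
    """
    pipeline = pipeline or PipelineConfig()
    if not isinstance(dataset, LabeledDataset):
        dataset = featurize_windows(dataset, pipeline)
    if folds is None:
        folds = stratified_folds(dataset.y, k, seed)
    k = int(folds.max()) + 1

    y_true_all = np.empty(len(dataset), dtype=int)
    y_pred_all = np.empty(len(dataset), dtype=int)
    proba_all = np.empty((len(dataset), len(dataset.classes)))
    per_fold = []
    for fold in range(k):
        test_mask = folds == fold
        train_set = dataset.subset(np.where(~test_mask)[0])
        test_idx = np.where(test_mask)[0]
        model = build_model(
            dataset.X.shape[1],
            dataset.classes,
            hidden_widths=pipeline.hidden_widths,
            dropout_rate=pipeline.training.dropout_rate,
            seed=seed + fold,
        )
        cfg = TrainingConfig(
            loss=pipeline.training.loss,
            learning_rate=pipeline.training.learning_rate,
            epochs=pipeline.training.epochs,
            batch_size=pipeline.training.batch_size,
            dropout_rate=pipeline.training.dropout_rate,
            splits=pipeline.training.splits,
            seed=seed + fold,
        )
        train(model, train_set, cfg, presplit=True)
        y_pred = predict_batch(model, dataset.X[test_idx])
        proba = predict_proba(model, dataset.X[test_idx])
        y_true_all[test_idx] = dataset.y[test_idx]
        y_pred_all[test_idx] = y_pred
        proba_all[test_idx] = proba
        frag = confusion_and_metrics(dataset.y[test_idx], y_pred, classes=dataset.classes)
        per_fold.append(
            {
                "fold": fold,
                "n_test": int(test_mask.sum()),
                "accuracy": frag.accuracy,
                "precision": frag.precision,
                "recall": frag.recall,
            }
        )
    report = confusion_and_metrics(
        y_true_all,
        y_pred_all,
        classes=dataset.classes,
        loss=_mean_crossentropy(proba_all, y_true_all, dataset.classes),
    )
    report.per_fold = per_fold
    report.config = {"k": k, "seed": seed, "pipeline": pipeline.__dict__ | {}}
    return report


def window_sweep(
    recordings: list[Recording],
    schedules: list,
    durations: list[float],
    pipeline: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV accuracy as a function of analysis-window duration.

    For each duration the recordings are re-segmented and re-featurized (the
    subwindow count scales with duration) and a fresh k-fold CV is run.  The
    output table is sorted by duration regardless of input order.
    """
    pipeline = pipeline or PipelineConfig()
    rows = []
    for duration in sorted(durations):
        windows = []
        for rec, sched in zip(recordings, schedules):
            windows.extend(segment(rec, sched, duration))
        report = kfold_cv(windows, k=k, pipeline=pipeline, seed=seed)
        rows.append(
            {
                "window_duration_s": duration,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
            }
        )
    return pd.DataFrame(rows)


def compare_feature_methods(
    windows: list[AnalysisWindow],
    methods: tuple[str, ...] = ("rms", "statistical"),
    pipeline: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side CV metrics per feature method on identical folds."""
    from dataclasses import replace

    pipeline = pipeline or PipelineConfig()
    labels = np.array([w.label for w in windows], dtype=int)
    folds = stratified_folds(labels, k, seed)
    rows = []
    for method in methods:
        mp = replace(pipeline, feature_method=method)
        report = kfold_cv(windows, k=k, pipeline=mp, seed=seed, folds=folds)
        rows.append(
            {
                "method": method,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "loss": report.loss,
            }
        )
    return pd.DataFrame(rows)
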