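"""Metrics, cross-validation and detection time series.

Metrics follow the usual multiclass conventions: accuracy is the diagonal
fraction of the confusion matrix (per-class recalls are reported alongside,
since "macro accuracy" is ambiguous); the AUC is macro-averaged over
one-vs-rest ROC curves (trapezoidal integration, ties contribute half);
the loss is the categorical cross-entropy of the score rows, with scores
clipped at 1e-12 so vote-frequency scores from trees and forests remain
finite.

Cross-validation is stratified over the ORIGINAL elements; when
augmentation is requested it is re-run inside each training fold, so no
augmented sibling of a validation element can leak into its training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierConfig, predict, train
from .config import FeatureConfig
from .dataset import CLASSES, AnnotatedElement, balance_augment
from .features import crop_features

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "DetectionTimeSeries",
    "confusion_matrix",
    "accuracy",
    "per_class_recall",
    "tpr_fpr",
    "macro_auc",
    "cross_entropy_loss",
    "cross_validate",
    "detection_time_series",
    "compare_series",
]


@dataclass
class ConfusionMatrix:
    """Count grid: rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} grid, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(
    truth: Sequence[str], pred: Sequence[str], classes: Sequence[str] = CLASSES
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a fixed-order count grid."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class schema: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Diagonal fraction; reduces to (TP+TN)/(TP+FP+TN+FN) for two classes."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_recall(cm: ConfusionMatrix) -> dict[str, float]:
    """Recall (diagonal / row sum) per class with at least one true element."""
    out = {}
    for i, c in enumerate(cm.classes):
        row = cm.counts[i].sum()
        if row > 0:
            out[c] = float(cm.counts[i, i] / row)
    return out


def tpr_fpr(cm: ConfusionMatrix, class_index: int) -> tuple[float, float]:
    """One-vs-rest sensitivity TP/(TP+FN) and fall-out FP/(FP+TN)."""
    tp = cm.counts[class_index, class_index]
    fn = cm.counts[class_index].sum() - tp
    fp = cm.counts[:, class_index].sum() - tp
    tn = cm.total - tp - fn - fp
    if tp + fn == 0:
        warnings.warn("no true elements of this class: TPR defined as 0")
        tpr = 0.0
    else:
        tpr = float(tp / (tp + fn))
    if fp + tn == 0:
        warnings.warn("no negative elements of this class: FPR defined as 0")
        fpr = 0.0
    else:
        fpr = float(fp / (fp + tn))
    return tpr, fpr


def macro_auc(
    scores: np.ndarray,
    truth: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> float:
    """Unweighted mean of one-vs-rest ROC AUCs over classes present in truth.

    Per-class curves use trapezoidal integration with score ties grouped,
    equal to the concordant-pair probability with half credit for ties.
    Classes absent from the truth are excluded with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(list(truth))
    if scores.ndim != 2 or scores.shape[0] != len(truth):
        raise ValueError("scores must be (n, n_classes) aligned with truth")
    present = set(truth)
    if len(present) < 2:
        raise ValueError("macro AUC needs at least 2 classes in the truth")
    aucs = []
    for j, c in enumerate(classes):
        if c not in present:
            warnings.warn(f"class {c!r} absent from truth; excluded from macro AUC")
            continue
        y = (truth == c).astype(int)
        aucs.append(roc_auc_score(y, scores[:, j]))
    return float(np.mean(aucs))


def cross_entropy_loss(
    scores: np.ndarray, truth: Sequence[str], classes: Sequence[str] = CLASSES
) -> float:
    """Mean categorical cross-entropy of the true-class score, clipped at 1e-12."""
    scores = np.asarray(scores, dtype=np.float64)
    index = {c: i for i, c in enumerate(classes)}
    idx = np.asarray([index[t] for t in truth])
    p = np.clip(scores[np.arange(len(idx)), idx], 1e-12, None)
    return float(-np.log(p).mean())


@dataclass
class EvaluationReport:
    """Cross-validated performance of one classifier configuration."""

    config_name: str
    seed: int
    folds: int
    accuracy: float
    macro_auc: float
    mean_loss: float
    fold_accuracy: list[float]
    fold_auc: list[float]
    fold_loss: list[float]
    confusion: ConfusionMatrix
    per_class_recall: dict[str, float] = field(default_factory=dict)
    #: validation element indices of each fold (a partition of the input)
    fold_indices: list[np.ndarray] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"classifier: {self.config_name} (seed {self.seed}, {self.folds}-fold CV)",
            f"accuracy:  {self.accuracy:.4f}",
            f"macro AUC: {self.macro_auc:.4f}",
            f"mean loss: {self.mean_loss:.4f}",
        ]
        return "\n".join(lines)


def cross_validate(
    config: ClassifierConfig,
    elements: Sequence[AnnotatedElement],
    folds: int = 10,
    seed: int = 0,
    augment_params: dict | None = None,
    feature_params: FeatureConfig | None = None,
    feature_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation over original elements.

    ``augment_params`` (keys accepted by :func:`balance_augment`) triggers
    balanced augmentation of each training fold; validation folds are never
    augmented.  Features of original elements are computed once and cached;
    augmented copies are featurized per fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray([e.label for e in elements])
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < folds]
    if len(small):
        raise ValueError(
            f"classes smaller than the fold count {folds}: {', '.join(small)}"
        )
    extract = feature_fn or (lambda crop: crop_features(crop, feature_params))
    cache = {id(e): extract(e.crop) for e in elements}

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    order = CLASSES if set(labels) <= set(CLASSES) else tuple(sorted(set(labels)))
    pooled_truth: list[str] = []
    pooled_pred: list[str] = []
    fold_acc: list[float] = []
    fold_auc: list[float] = []
    fold_loss: list[float] = []
    fold_indices: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for fold_idx, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_indices.append(va_idx)
        train_elems = [elements[i] for i in tr_idx]
        if augment_params:
            train_elems = balance_augment(train_elems, rng=rng, **augment_params)
        X_tr = np.asarray([
            cache[id(e)] if id(e) in cache else extract(e.crop) for e in train_elems
        ])
        y_tr = [e.label for e in train_elems]
        X_va = np.asarray([cache[id(elements[i])] for i in va_idx])
        y_va = [elements[i].label for i in va_idx]
        fold_config = ClassifierConfig(
            name=config.name, family=config.family, hyper=dict(config.hyper),
            train_params=dict(config.train_params), seed=config.seed + fold_idx,
        )
        model = train(fold_config, X_tr, y_tr)
        pred, scores = predict(model, X_va)
        cm = confusion_matrix(y_va, pred, order)
        fold_acc.append(accuracy(cm))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_auc.append(macro_auc(scores, y_va, model.class_order))
        fold_loss.append(cross_entropy_loss(scores, y_va, model.class_order))
        pooled_truth.extend(y_va)
        pooled_pred.extend(pred)
    pooled_cm = confusion_matrix(pooled_truth, pooled_pred, order)
    return EvaluationReport(
        config_name=config.name,
        seed=seed,
        folds=folds,
        accuracy=float(np.mean(fold_acc)),
        macro_auc=float(np.mean(fold_auc)),
        mean_loss=float(np.mean(fold_loss)),
        fold_accuracy=fold_acc,
        fold_auc=fold_auc,
        fold_loss=fold_loss,
        confusion=pooled_cm,
        per_class_recall=per_class_recall(pooled_cm),
        fold_indices=fold_indices,
    )


@dataclass
class DetectionTimeSeries:
    """Per-day detection counts of one class from one counting method."""

    class_label: str
    points: list[tuple[date, int]]
    source: str = "automatic"  # "automatic" | "manual"
    images_with_detection: int | None = None

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if any(c < 0 for _, c in self.points):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(c for _, c in self.points)


def detection_time_series(
    records: Sequence[tuple[str, date, str]] | pd.DataFrame,
    class_label: str,
    date_range: tuple[date, date] | None = None,
    source: str = "automatic",
) -> DetectionTimeSeries:
    """Per-date counts of classified detections of one class.

    ``records`` holds (image_id, date, label) triples.  Dates inside the
    range with no detections are reported as 0.  Also counts the number of
    distinct images containing at least one detection of the class.
    """
    if isinstance(records, pd.DataFrame):
        rows = list(records[["image_id", "date", "label"]].itertuples(index=False))
    else:
        rows = list(records)
    rows = [(img, d, lab) for img, d, lab in rows if lab == class_label]
    if date_range is None:
        if not rows:
            return DetectionTimeSeries(class_label, [], source, 0)
        dates = [d for _, d, _ in rows]
        date_range = (min(dates), max(dates))
    start, end = date_range
    counts: dict[date, int] = {}
    d = start
    while d <= end:
        counts[d] = 0
        d += timedelta(days=1)
    images: set[str] = set()
    for img, d, _ in rows:
        if start <= d <= end:
            counts[d] += 1
            images.add(img)
    return DetectionTimeSeries(
        class_label, sorted(counts.items()), source, len(images)
    )


def compare_series(
    auto: DetectionTimeSeries, manual: DetectionTimeSeries
) -> pd.DataFrame:
    """Align automatic and manual counts: per-date difference plus totals.

    Returns a frame with one row per date (auto, manual, difference) and
    attrs recording the totals and, per source, the number of images with
    at least one detection.
    """
    if auto.class_label != manual.class_label:
        raise ValueError("series compare different classes")
    d_a = [d for d, _ in auto.points]
    d_m = [d for d, _ in manual.points]
    if d_a != d_m:
        raise ValueError("series date ranges differ")
    df = pd.DataFrame(
        {
            "date": d_a,
            "auto": [c for _, c in auto.points],
            "manual": [c for _, c in manual.points],
        }
    )
    df["difference"] = df["auto"] - df["manual"]
    df.attrs["auto_total"] = auto.total
    df.attrs["manual_total"] = manual.total
    df.attrs["auto_images_with_detection"] = auto.images_with_detection
    df.attrs["manual_images_with_detection"] = manual.images_with_detection
    return df
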