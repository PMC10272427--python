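"""Confusion matrix and support-weighted multi-class metrics.

For an n-class problem the confusion matrix X has X[i, j] = number of
samples of actual class i predicted as class j.  Per class i,

    TP_i = X_ii            FP_i = column-sum_i - TP_i
    FN_i = row-sum_i - TP_i
    TN_i = total - TP_i - FP_i - FN_i
    support_i = row-sum_i = TP_i + FN_i

Accuracy is trace/total; recall, precision and specificity are
support-weighted averages of the per-class one-vs-rest rates; F1 is the
harmonic mean of the weighted precision and recall (a flag offers the
support-weighted mean of per-class F1 scores instead); AUC is the
support-weighted average of per-class one-vs-rest ROC AUCs.

Note the algebraic identity: the support-weighted recall
sum_i TP_i / sum_i support_i equals the accuracy trace/total for every
confusion matrix.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "PerClassCounts",
    "MetricsReport",
    "confusion_matrix",
    "per_class_counts",
    "accuracy",
    "weighted_metric",
    "weighted_f1",
    "weighted_auc",
    "compute_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n, n) int array, rows = actual, columns = predicted
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")
        if len(self.class_names) != self.counts.shape[0]:
            raise ValueError("class_names length must match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["actual\\predicted"] + list(self.class_names))
            for name, row in zip(self.class_names, self.counts):
                writer.writerow([name] + [int(v) for v in row])


@dataclass
class PerClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def support(self) -> int:
        return self.tp + self.fn


def confusion_matrix(y_true, y_pred, n_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d label vectors")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    names = class_names or [str(i) for i in range(n_classes)]
    return ConfusionMatrix(counts, list(names))


def per_class_counts(cm: ConfusionMatrix, i: int) -> PerClassCounts:
    x = cm.counts
    tp = int(x[i, i])
    fp = int(x[:, i].sum()) - tp
    fn = int(x[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts)) / cm.total


def _safe_rate(num: int, den: int, what: str, cls: str) -> float:
    # 0/0 (e.g. no predicted positives for a class) -> 0, conservatively
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls} (0/0); using 0", stacklevel=3)
        return 0.0
    return num / den


def weighted_metric(cm: ConfusionMatrix, kind: str) -> float:
    """Support-weighted recall, precision or specificity."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    if kind not in ("recall", "precision", "specificity"):
        raise ValueError(f"kind must be recall/precision/specificity, got {kind!r}")
    num = 0.0
    total_support = 0
    for i in range(cm.n_classes):
        c = per_class_counts(cm, i)
        if kind == "recall":
            rate = _safe_rate(c.tp, c.tp + c.fn, kind, cm.class_names[i])
        elif kind == "precision":
            rate = _safe_rate(c.tp, c.tp + c.fp, kind, cm.class_names[i])
        else:
            rate = _safe_rate(c.tn, c.tn + c.fp, kind, cm.class_names[i])
        num += rate * c.support
        total_support += c.support
    return num / total_support


def weighted_f1(cm: ConfusionMatrix, from_per_class: bool = False) -> float:
    """Harmonic mean of the weighted precision and recall.

    With ``from_per_class=True``, returns instead the support-weighted
    mean of per-class F1 scores (the scikit-learn "weighted" convention).
    """
    if from_per_class:
        num = 0.0
        total_support = 0
        for i in range(cm.n_classes):
            c = per_class_counts(cm, i)
            p = _safe_rate(c.tp, c.tp + c.fp, "precision", cm.class_names[i])
            r = _safe_rate(c.tp, c.tp + c.fn, "recall", cm.class_names[i])
            f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            num += f1 * c.support
            total_support += c.support
        return num / total_support
    p = weighted_metric(cm, "precision")
    r = weighted_metric(cm, "recall")
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def weighted_auc(y_true, score_matrix) -> float:
    """Support-weighted one-vs-rest ROC AUC.

    ``score_matrix`` rows are per-sample class scores.  A class absent
    from ``y_true`` has an undefined AUC; it is excluded and the weights
    renormalised (with a warning).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(score_matrix, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("score_matrix must be (n_samples, n_classes)")
    n_classes = scores.shape[1]
    aucs, supports = [], []
    for i in range(n_classes):
        pos = y_true == i
        support = int(pos.sum())
        if support == 0 or support == len(y_true):
            warnings.warn(
                f"class {i} has no positives or no negatives; excluded from weighted AUC",
                stacklevel=2,
            )
            continue
        aucs.append(roc_auc_score(pos.astype(int), scores[:, i]))
        supports.append(support)
    if not aucs:
        raise ValueError("weighted AUC undefined: no class has both positives and negatives")
    supports = np.asarray(supports, dtype=np.float64)
    return float(np.dot(aucs, supports) / supports.sum())


@dataclass
class MetricsReport:
    """Weighted metric bundle with per-class detail."""

    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    auc: float | None
    per_class: dict[str, dict[str, float]]
    confusion: list[list[int]]
    class_names: list[str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key in ("accuracy", "recall", "precision", "specificity", "f1", "auc"):
                writer.writerow([key, getattr(self, key)])


def compute_report(y_true, y_pred, score_matrix=None,
                   class_names: list[str] | None = None) -> MetricsReport:
    """Confusion matrix -> full weighted report (AUC only if scores given)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if score_matrix is not None:
        n_classes = np.asarray(score_matrix).shape[1]
    else:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    if class_names is not None:
        n_classes = max(n_classes, len(class_names))
    cm = confusion_matrix(y_true, y_pred, n_classes, class_names)
    per_class = {}
    for i, name in enumerate(cm.class_names):
        c = per_class_counts(cm, i)
        per_class[name] = {
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn, "support": c.support,
            "recall": _safe_rate(c.tp, c.tp + c.fn, "recall", name),
            "precision": _safe_rate(c.tp, c.tp + c.fp, "precision", name),
            "specificity": _safe_rate(c.tn, c.tn + c.fp, "specificity", name),
        }
    auc = weighted_auc(y_true, score_matrix) if score_matrix is not None else None
    return MetricsReport(
        accuracy=accuracy(cm),
        recall=weighted_metric(cm, "recall"),
        precision=weighted_metric(cm, "precision"),
        specificity=weighted_metric(cm, "specificity"),
        f1=weighted_f1(cm),
        auc=auc,
        per_class=per_class,
        confusion=cm.counts.tolist(),
        class_names=list(cm.class_names),
    )
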