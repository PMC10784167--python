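"""Confusion-matrix based classification metrics.

Binary metrics follow the textbook TP/TN/FP/FN formulas (accuracy,
sensitivity = recall, precision, F1); the multiclass case reduces each
class one-vs-rest and macro-averages.  Reports serialize to JSON/CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "classification_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count table, true class on rows, predicted class on columns."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c`` against the rest."""
        cm = self.counts
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = int(cm.sum() - tp - fp - fn)
        return tp, fp, fn, tn

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts).to_csv(path, index=False)


@dataclass
class MetricsReport:
    """Overall and per-class accuracy/sensitivity/precision/F1."""

    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    per_class: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "per_class": {k: np.asarray(v).tolist() for k, v in self.per_class.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Tally counts[t][p] over paired integer labels in [0, n_classes)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as 0", what)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix | np.ndarray) -> MetricsReport:
    """Accuracy, sensitivity, precision and F1 from a confusion matrix.

    Two classes use the binary formulas directly (class 1 treated as
    positive); more classes are macro-averaged one-vs-rest.  All outputs
    lie in [0, 1]; undefined ratios (empty denominators) are 0.
    """
    if not isinstance(cm, ConfusionMatrix):
        cm = ConfusionMatrix(cm)
    if cm.total < 1:
        raise ValueError("confusion matrix must score at least one sample")

    if cm.n_classes == 2:
        tp, fp, fn, tn = cm.one_vs_rest(1)
        acc = (tp + tn) / (tp + tn + fp + fn)
        sens = _safe_div(tp, tp + fn, "sensitivity")
        prec = _safe_div(tp, tp + fp, "precision")
        f1 = _safe_div(2.0 * sens * prec, sens + prec, "F1")
        return MetricsReport(accuracy=acc, sensitivity=sens, precision=prec, f1=f1)

    n = cm.n_classes
    accs = np.empty(n)
    senss = np.empty(n)
    precs = np.empty(n)
    f1s = np.empty(n)
    for c in range(n):
        tp, fp, fn, tn = cm.one_vs_rest(c)
        accs[c] = (tp + tn) / cm.total
        senss[c] = _safe_div(tp, tp + fn, f"sensitivity[{c}]")
        precs[c] = _safe_div(tp, tp + fp, f"precision[{c}]")
        f1s[c] = _safe_div(2 * senss[c] * precs[c], senss[c] + precs[c], f"F1[{c}]")
    overall_acc = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(
        accuracy=overall_acc,
        sensitivity=float(senss.mean()),
        precision=float(precs.mean()),
        f1=float(f1s.mean()),
        per_class={
            "accuracy": accs, "sensitivity": senss,
            "precision": precs, "f1": f1s,
        },
    )
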