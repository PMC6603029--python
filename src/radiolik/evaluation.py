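"""Threshold classification, confusion matrices, and ROC/AUC.

The positive class is malignant (label 1).  A nodule is called
malignant when its likelihood score satisfies y >= threshold, with
0.51 the published operating point.

Two naming conventions for the ratio metrics coexist in the radiomics
literature, and this module exposes both explicitly rather than picking
silently:

* ``paper_sensitivity`` = TP / (TP + FP) and
  ``paper_specificity`` = TN / (TN + FN) — the convention under which
  the reference confusion matrices reproduce their published
  sensitivity/specificity percentages (these are the positive and
  negative predictive values in standard epidemiological terms);
* ``std_sensitivity`` = TP / (TP + FN) and
  ``std_specificity`` = TN / (TN + FP) — the standard recall-style
  definitions, also used for the ROC axes.

Accuracy is (TP + TN) / (TP + FN + FP + TN) under either convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "classify",
    "confusion",
    "metrics",
    "roc_auc",
]

DEFAULT_THRESHOLD = 0.51


def classify(y: float | np.ndarray, threshold: float = DEFAULT_THRESHOLD):
    """Label a score (or score vector): 1 (malignant) iff y >= threshold."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite score")
    labels = (y >= threshold).astype(int)
    return int(labels) if labels.ndim == 0 else labels


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = malignant: TP, FN, FP, TN."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(
    true_labels: Sequence[int], pred_labels: Sequence[int]
) -> ConfusionMatrix:
    """Tally a confusion matrix from paired binary label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("labels must be non-empty 1-D vectors of equal length")
    for v, name in ((t, "true"), (p, "pred")):
        if not np.isin(v, [0, 1]).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
    )


@dataclass
class EvalReport:
    """Scalar metrics (plus optional ROC) derived from a confusion matrix."""

    cm: ConfusionMatrix
    accuracy: float | None
    paper_sensitivity: float | None
    paper_specificity: float | None
    std_sensitivity: float | None
    std_specificity: float | None
    roc: list[tuple[float, float]] | None = field(default=None)
    auc: float | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.cm.tp, "fn": self.cm.fn,
                "fp": self.cm.fp, "tn": self.cm.tn,
            },
            "accuracy": self.accuracy,
            "paper_sensitivity": self.paper_sensitivity,
            "paper_specificity": self.paper_specificity,
            "std_sensitivity": self.std_sensitivity,
            "std_specificity": self.std_specificity,
            "roc": self.roc,
            "auc": self.auc,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Compute all ratio metrics from a confusion matrix.

    Ratios with zero denominators are reported as ``None`` with a
    warning rather than NaN.
    """
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    return EvalReport(
        cm=cm,
        accuracy=(cm.tp + cm.tn) / cm.total,
        paper_sensitivity=_ratio(cm.tp, cm.tp + cm.fp, "paper_sensitivity"),
        paper_specificity=_ratio(cm.tn, cm.tn + cm.fn, "paper_specificity"),
        std_sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "std_sensitivity"),
        std_specificity=_ratio(cm.tn, cm.tn + cm.fp, "std_specificity"),
    )


def roc_auc(
    scores: Sequence[float], true_labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and trapezoidal AUC for the rule "positive iff y >= t".

    The threshold sweeps the distinct observed scores (ties grouped into
    a single step) plus the endpoints where everything / nothing is
    called positive.  Axes are the standard TPR = TP/(TP+FN) and
    FPR = FP/(FP+TN).
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    if scores.shape != t.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if np.unique(t).size != 2 or not np.isin(t, [0, 1]).all():
        raise ValueError("need both classes present with 0/1 labels")
    fpr, tpr, _ = roc_curve(t, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = [(float(f), float(s)) for f, s in zip(fpr, tpr)]
    return points, auc
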