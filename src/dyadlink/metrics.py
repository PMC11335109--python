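"""Evaluation statistics: MAE, R^2, accuracy/confusion, macro one-vs-rest AUC.

MAE and R^2 treat the behavior target through its ordinal codes 0/1/2, since
the ensemble's combination rule operates on numeric predictions.  Multiclass
AUC is the unweighted mean of per-class one-vs-rest ROC areas (Mann-Whitney
rank form, ties counting one half), the most common multiclass convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .schema import DyadlinkError

logger = logging.getLogger(__name__)

__all__ = [
    "mae",
    "r_squared",
    "confusion_and_accuracy",
    "auc_macro_ovr",
    "EvaluationReport",
]


def mae(y_true, y_pred) -> float:
    """Mean absolute error (1/N) * sum |y_i - yhat_i|."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal shapes")
    if y_true.size == 0:
        raise ValueError("MAE of an empty vector is undefined")
    return float(np.mean(np.abs(y_true - y_pred)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (<= 1, unbounded below)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise DyadlinkError("R^2 undefined: y_true is constant")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


def confusion_and_accuracy(
    y_true, y_pred, labels: tuple[int, ...] = (0, 1, 2)
) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows = true class) and overall accuracy.

    Both label vectors must stay within ``labels`` (default: the three
    behavior classes).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    label_set = set(labels)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        outside = set(np.unique(y)) - label_set
        if outside:
            raise ValueError(f"{name} contains labels outside {labels}: {sorted(outside)}")
    cm = _sk_confusion(y_true, y_pred, labels=list(labels))
    accuracy = float(np.trace(cm)) / float(cm.sum())
    return cm, accuracy


def auc_macro_ovr(y_true, scores) -> float:
    """Macro one-vs-rest AUC from a per-class score matrix.

    Each class present in ``y_true`` contributes its binary rank-based ROC
    area (class column vs. the rest); absent classes are excluded with a log
    message.  A single-class truth vector has no defined AUC.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be an (n_samples, n_classes) matrix")
    present = np.unique(y_true)
    if present.size < 2:
        raise DyadlinkError("AUC undefined: only one class present in y_true")
    aucs = []
    for cls in range(scores.shape[1]):
        if cls not in present:
            logger.info("class %d absent from y_true; excluded from macro AUC", cls)
            continue
        aucs.append(roc_auc_score((y_true == cls).astype(int), scores[:, cls]))
    return float(np.mean(aucs))


@dataclass
class EvaluationReport:
    """Per-model, per-split metric table.

    ``metrics[model][split]`` maps metric name -> value; confusion matrices
    are stored separately as integer arrays.
    """

    metrics: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    confusions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def record(
        self,
        model: str,
        split: str,
        *,
        accuracy: float | None = None,
        auc: float | None = None,
        mae: float | None = None,
        r2: float | None = None,
        confusion: np.ndarray | None = None,
    ) -> None:
        entry = self.metrics.setdefault(model, {}).setdefault(split, {})
        for name, value in (("accuracy", accuracy), ("auc", auc), ("mae", mae), ("r2", r2)):
            if value is not None:
                entry[name] = float(value)
        if confusion is not None:
            self.confusions.setdefault(model, {})[split] = np.asarray(confusion)

    def to_frame(self) -> pd.DataFrame:
        """Model x split table (one row per model/split, metric columns)."""
        rows = []
        for model, splits in self.metrics.items():
            for split, entry in splits.items():
                rows.append({"model": model, "split": split, **entry})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "metrics": self.metrics,
            "confusions": {
                model: {split: cm.tolist() for split, cm in splits.items()}
                for model, splits in self.confusions.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)
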