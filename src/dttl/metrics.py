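"""Held-out evaluation: ROC/AUC and per-class diagnostics.

The minority ("lesion present") class is the positive class everywhere.
AUC follows the Mann-Whitney convention — the probability that a random
minority sample outscores a random majority sample, ties counting 1/2 —
and the ROC curve is swept over all unique score thresholds so that the
trapezoidal area under it reproduces the AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .data import MAJ, MIN

__all__ = ["EvalReport", "auc", "roc_curve", "classification_report", "evaluate"]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape[0] != labels.shape[0] or scores.shape[0] == 0:
        raise ValueError("scores and labels must be non-empty and aligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined for single-class labels")
    return scores, labels


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve with the minority class positive."""
    scores, labels = _validate(scores, labels)
    return float(skm.roc_auc_score(labels == MIN, scores))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) rows over all unique score thresholds."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = skm.roc_curve(labels == MIN, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr, thr])


def classification_report(pred_labels: np.ndarray, true_labels: np.ndarray) -> dict:
    """Per-class recall and balanced accuracy."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if true.size == 0:
        raise ValueError("empty evaluation set")
    out = {}
    for cls, name in ((MAJ, "recall_maj"), (MIN, "recall_min")):
        mask = true == cls
        out[name] = float(np.mean(pred[mask] == cls)) if mask.any() else float("nan")
    out["balanced_accuracy"] = float(np.nanmean([out["recall_maj"], out["recall_min"]]))
    return out


@dataclass
class EvalReport:
    auc: float
    roc_points: np.ndarray            # (k, 3): fpr, tpr, threshold
    per_class_recall: dict[str, float]
    balanced_accuracy: float
    n_eval: int

    def to_json(self, path: str | Path) -> None:
        payload = {"auc": self.auc, "recall_maj": self.per_class_recall["maj"],
                   "recall_min": self.per_class_recall["min"],
                   "balanced_accuracy": self.balanced_accuracy, "n_eval": self.n_eval}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def roc_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr", "threshold"]).to_csv(
            path, index=False)


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Full evaluation report from minority scores and true labels."""
    a = auc(scores, labels)
    roc = roc_curve(scores, labels)
    pred = np.where(np.asarray(scores) >= threshold, MIN, MAJ)
    rep = classification_report(pred, labels)
    return EvalReport(
        auc=a, roc_points=roc,
        per_class_recall={"maj": rep["recall_maj"], "min": rep["recall_min"]},
        balanced_accuracy=rep["balanced_accuracy"],
        n_eval=int(len(labels)),
    )
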