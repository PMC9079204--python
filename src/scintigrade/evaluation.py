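"""ROC/accuracy/precision-recall evaluation and subgroup reports.

Binary tasks are scored with ROC-AUC on the positive-class probability;
the four-class task uses macro-averaged one-vs-rest AUC over the four
probability outputs. Precision and recall are per class with undefined
ratios reported as NaN (never silently zero). Cross-validated metrics are
computed on the pooled out-of-fold predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _confusion
from sklearn.metrics import precision_score, recall_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "evaluate_predictions", "evaluate",
           "subgroup_report", "binary_auc_brute_force"]


@dataclass
class EvaluationReport:
    """Metrics for one classification task (optionally one subgroup)."""

    task: str
    auc: float
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    confusion: np.ndarray
    n: int
    subgroup: str = "all"

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "subgroup": self.subgroup,
            "n": int(self.n),
            "auc": None if np.isnan(self.auc) else float(self.auc),
            "accuracy": None if np.isnan(self.accuracy) else float(self.accuracy),
            "precision": [None if np.isnan(v) else float(v) for v in self.precision],
            "recall": [None if np.isnan(v) else float(v) for v in self.recall],
            "confusion": self.confusion.astype(int).tolist(),
        }


def _auc(y: np.ndarray, probs: np.ndarray) -> float:
    classes = np.unique(y)
    n_classes = probs.shape[1]
    if classes.size < 2:
        logger.warning("single-class test set: AUC undefined")
        return float("nan")
    try:
        if n_classes == 2:
            return float(roc_auc_score(y, probs[:, 1]))
        if classes.size < n_classes:
            logger.warning("test set lacks %d of %d classes: macro-OVR AUC "
                           "restricted to present classes",
                           n_classes - classes.size, n_classes)
            present = [roc_auc_score((y == c).astype(int), probs[:, c])
                       for c in classes]
            return float(np.mean(present))
        return float(roc_auc_score(y, probs, multi_class="ovr", average="macro"))
    except ValueError as e:  # pragma: no cover - defensive
        logger.warning("AUC undefined: %s", e)
        return float("nan")


def evaluate_predictions(y_true, probs, task: str,
                         subgroup: str = "all") -> EvaluationReport:
    """Score predicted class probabilities against true labels."""
    y = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    if len(y) == 0:
        logger.warning("empty evaluation set (%s/%s)", task, subgroup)
        k = probs.shape[1] if probs.ndim == 2 else 2
        return EvaluationReport(task, np.nan, np.nan,
                                np.full(k, np.nan), np.full(k, np.nan),
                                np.zeros((k, k), dtype=int), 0, subgroup)
    k = probs.shape[1]
    labels = np.arange(k)
    pred = probs.argmax(axis=1)
    cm = _confusion(y, pred, labels=labels)
    acc = float(np.trace(cm) / cm.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec = precision_score(y, pred, labels=labels, average=None,
                               zero_division=np.nan)
        rec = recall_score(y, pred, labels=labels, average=None,
                           zero_division=np.nan)
    return EvaluationReport(task, _auc(y, probs), acc, np.asarray(prec),
                            np.asarray(rec), cm, len(y), subgroup)


def evaluate(handle, test_images, test_labels, task: str) -> EvaluationReport:
    """Run a trained network on a test set and score it."""
    probs = handle.predict_proba(np.asarray(test_images, dtype=np.float32))
    return evaluate_predictions(test_labels, probs, task)


def subgroup_report(predictions: pd.DataFrame, task: str) -> dict[str, EvaluationReport]:
    """Split pooled out-of-fold predictions by the bone-metastasis flag and
    score each group with identical metric definitions.

    ``predictions`` needs columns ``y_true``, ``has_metastases`` and
    ``p0..p{k-1}``.
    """
    pcols = [c for c in predictions.columns if c.startswith("p")
             and c[1:].isdigit()]
    out = {}
    for name, flag in (("metastases", True), ("no_metastases", False)):
        sub = predictions[predictions["has_metastases"] == flag]
        out[name] = evaluate_predictions(
            sub["y_true"].to_numpy(), sub[pcols].to_numpy(), task, subgroup=name
        )
    return out


def binary_auc_brute_force(y_true, scores) -> float:
    """All-pairs concordance count: P(score+ > score-) + 0.5 P(tie).

    Independent O(n^2) oracle for the ROC-AUC of a binary problem.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
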