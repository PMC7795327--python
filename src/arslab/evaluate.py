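"""Classification metrics with one-vs-all reduction.

Accuracy, precision, sensitivity, F1 and the Matthews correlation
coefficient are computed from binary (TP, TN, FP, FN) counts; a multiclass
confusion matrix is collapsed one-vs-all per class.  Zero-denominator
conventions (all total functions): precision, sensitivity and F1 are 0 when
undefined, and MCC is 0 when any marginal is zero — degenerate all-one-class
predictors therefore score MCC 0 rather than NaN.  The area under the ROC
curve is the Mann-Whitney probability with half credit for score ties, and
is reported for binary tasks only.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion

from .exceptions import ValidationError

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "mcc")


def confusion(y_true, y_pred, labels) -> np.ndarray:
    """Integer confusion matrix, rows = true class, columns = predicted."""
    cm = _sk_confusion(y_true, y_pred, labels=list(labels))
    if cm.sum() == 0:
        raise ValidationError("empty confusion matrix")
    return cm


def one_vs_all_counts(cm: np.ndarray, class_index: int) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for one class of a multiclass confusion matrix."""
    cm = np.asarray(cm)
    tp = int(cm[class_index, class_index])
    fn = int(cm[class_index].sum() - tp)
    fp = int(cm[:, class_index].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, tn, fp, fn


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """The five study metrics from binary counts."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn) - (fp * fn)) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
        "mcc": float(mcc),
    }


def metrics_from_confusion(cm: np.ndarray, positive_index: int) -> dict[str, float]:
    """One-vs-all metrics for one class of a (possibly multiclass) matrix."""
    return binary_metrics(*one_vs_all_counts(cm, positive_index))


def multiclass_accuracy(cm: np.ndarray) -> float:
    """Overall accuracy: trace over total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm) / total)


def auc_binary(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney probability.

    ``labels`` are boolean/0-1 (positive class = truthy); ties in ``scores``
    receive half credit via midranks.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("auc_binary requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


__all__ = [
    "METRIC_NAMES",
    "confusion",
    "one_vs_all_counts",
    "binary_metrics",
    "metrics_from_confusion",
    "multiclass_accuracy",
    "auc_binary",
]
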