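"""Classification metrics for the QC comparison.

Binary metrics treat *outlier* as the positive class; the 2x2 confusion
matrix convention is rows = actual, columns = predicted, with the top
row the valid (inlier) class — matching how the comparison tables are
reported.
"""
from __future__ import annotations

import numpy as np


def confusion(y_true, y_pred, classes) -> np.ndarray:
    """k x k count matrix; entry (i, j) = actual classes[i] predicted
    classes[j]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: true={t} pred={p}")
        cm[index[t], index[p]] += 1
    return cm


def _binary_cells(cm: np.ndarray):
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise ValueError("binary metrics need a 2x2 confusion matrix")
    tn, fp = int(cm[0, 0]), int(cm[0, 1])
    fn, tp = int(cm[1, 0]), int(cm[1, 1])
    return tp, tn, fp, fn


def mcc(cm: np.ndarray) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix;
    defined as 0 when any marginal is zero."""
    tp, tn, fp, fn = _binary_cells(cm)
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def f1(cm: np.ndarray) -> float:
    """F1-score of a 2x2 confusion matrix (outlier = positive class)."""
    tp, tn, fp, fn = _binary_cells(cm)
    if tp == 0:
        return 0.0 if (fp + fn) > 0 else 1.0
    return float(2 * tp / (2 * tp + fp + fn))


def binary_confusion(y_true_outlier, y_pred_outlier) -> np.ndarray:
    """2x2 matrix from boolean outlier flags (row 0 = valid)."""
    t = np.asarray(y_true_outlier).astype(int)
    p = np.asarray(y_pred_outlier).astype(int)
    return confusion(t, p, classes=[0, 1])


def binary_mcc(y_true_outlier, y_pred_outlier) -> float:
    return mcc(binary_confusion(y_true_outlier, y_pred_outlier))


def binary_f1(y_true_outlier, y_pred_outlier) -> float:
    return f1(binary_confusion(y_true_outlier, y_pred_outlier))
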