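"""Classification metrics, ROC/AUC, Pearson correlation, sample size.

Conventions: class 1 is the positive class; the confusion matrix is
[[TN, FP], [FN, TP]]; precision/recall/F1 are macro-averaged over the two
classes, with 0/0 ratios reported as 0 (a warning is emitted, the class is
not dropped from the macro mean). AUC uses the rank (Mann-Whitney)
formulation — the probability that a random positive scores above a random
negative — with ties counted one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """2x2 count matrix, rows = truth, cols = prediction, class 1 positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if set(np.unique(arr)) - {0, 1}:
            raise ValueError(f"{name} must contain only 0/1 labels")
    cm = np.zeros((2, 2), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (0/0) reported as 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: np.ndarray) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 from a 2x2 confusion matrix."""
    cm = np.asarray(cm)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 and nonnegative")
    n = int(cm.sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    precisions, recalls, f1s = [], [], []
    for c in (0, 1):
        tp = cm[c, c]
        prec = _ratio(tp, cm[:, c].sum(), f"precision of class {c}")
        rec = _ratio(tp, cm[c, :].sum(), f"recall of class {c}")
        f1 = _ratio(2 * prec * rec, prec + rec, f"F1 of class {c}")
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return {
        "accuracy": float(np.trace(cm)) / n,
        "precision_macro": float(np.mean(precisions)),
        "recall_macro": float(np.mean(recalls)),
        "f1_macro": float(np.mean(f1s)),
    }


def roc_auc(y_true, scores) -> tuple[float, list[tuple[float, float]]]:
    """Rank-form AUC plus the ROC polyline over distinct score thresholds.

    Returns ``(auc, [(fpr, tpr), ...])`` starting at (0, 0) and ending at
    (1, 1). Requires both classes in ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = 1 if n_pos == 0 else 0
        raise ValueError(f"class {missing} absent from y_true; AUC undefined")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # ROC points: sweep thresholds downward through the distinct scores
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    sorted_scores = scores[order]
    sorted_truth = y_true[order]
    i = 0
    while i < len(sorted_scores):
        j = i
        while j < len(sorted_scores) and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_truth[j] == 1)
            fp += int(sorted_truth[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return float(auc), points


def correlation_report(
    frame: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson r over numeric columns.

    With ``pairs`` given, returns a long table (var_a, var_b, r); otherwise
    the full symmetric matrix. Constant columns yield NaN entries and a
    warning rather than a fabricated 0.
    """
    num = frame.select_dtypes(include=[np.number])
    sds = num.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(
            f"constant columns have undefined correlations (NaN): {constant}",
            stacklevel=2,
        )
    if pairs is None:
        return num.corr(method="pearson")
    rows = []
    for a, b in pairs:
        r = num[a].corr(num[b], method="pearson")
        rows.append({"var_a": a, "var_b": b, "pearson_r": r})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Single-proportion sample-size inputs: n = Z^2 P (1-P) / d^2."""

    z: float = 1.96
    p: float = 0.65
    d: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("prevalence p must lie strictly in (0, 1)")
        if self.d <= 0:
            raise ValueError("precision d must be positive")


def sample_size(spec: SampleSizeSpec) -> int:
    """Minimum cohort size for estimating a prevalence to precision d.

    Ceiling of Z^2 * P * (1 - P) / d^2, with a floor of 1.
    """
    raw = spec.z**2 * spec.p * (1.0 - spec.p) / spec.d**2
    return max(1, math.ceil(raw))
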