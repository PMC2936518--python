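"""ROC/AUC, precision-recall and thresholded SL calls.

AUC follows the Mann–Whitney formulation: the probability that a
uniformly random positive outscores a uniformly random negative, with
ties counted 0.5.  Curves are computed at every distinct score; a call
is positive iff score >= threshold.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["roc_auc", "pr_curve", "call_interactions"]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC curve points and the AUC.

    Returns (curve, auc) where curve has columns (threshold, fpr, tpr).
    Raises on single-class labels, for which the ROC is undefined.
    """
    s, y = _validate(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(roc_auc_score(y, s))


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """Precision and recall at every distinct score threshold.

    A prediction is positive iff score >= threshold.  The zero-
    prediction limit (threshold above the maximum score) is anchored at
    precision 1, recall 0 by convention.  Columns: (threshold,
    recall, precision).
    """
    s, y = _validate(scores, labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("precision-recall needs at least one positive")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted == 1)
    n_pred = np.arange(1, len(s) + 1)
    # collapse tied scores: keep the last entry of each tie block
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    thresholds = s_sorted[is_last]
    precision = tp[is_last] / n_pred[is_last]
    recall = tp[is_last] / n_pos
    out = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, thresholds],
            "recall": np.r_[0.0, recall],
            "precision": np.r_[1.0, precision],
        }
    )
    return out


def call_interactions(
    scores: Sequence[float], threshold: float = 0.2
) -> tuple[np.ndarray, dict]:
    """Binary SL calls at a score threshold (call SL iff score >= t).

    Returns (calls, summary) where summary counts calls per class.
    """
    s = np.asarray(scores, dtype=float)
    calls = s >= threshold
    summary = {
        "threshold": float(threshold),
        "n": int(s.size),
        "n_sl": int(calls.sum()),
        "n_non_sl": int((~calls).sum()),
    }
    return calls, summary


def write_predictions(
    index: pd.MultiIndex,
    scores: Sequence[float],
    path: str | Path,
    threshold: float = 0.2,
) -> None:
    """Predictions TSV: geneA, geneB, score, call (SL / nonSL)."""
    calls, _ = call_interactions(scores, threshold)
    df = pd.DataFrame(
        {
            "geneA": [a for a, _ in index],
            "geneB": [b for _, b in index],
            "score": np.asarray(scores, dtype=float),
            "call": np.where(calls, "SL", "nonSL"),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
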