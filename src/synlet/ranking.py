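"""Feature ranking by two-sample Kolmogorov–Smirnov discriminative power.

For each feature, the D-statistic — the supremum distance between the
empirical CDFs of the feature in the positive (SL) and negative (non-SL)
classes — measures how well that feature alone separates the classes.
Missing cells are dropped per feature (pairwise deletion); imputation is
a modelling step and has no place in a descriptive ranking.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ks_d_statistic", "rank_features"]


def ks_d_statistic(pos_values: Sequence[float], neg_values: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_pos - ECDF_neg| and its
    asymptotic p-value.

    Both samples must be non-empty after missing-value removal.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(pos, neg, method="asymp")
    return float(res.statistic), float(res.pvalue)


def rank_features(matrix: pd.DataFrame, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Rank every feature by its KS D-statistic, descending.

    ``labels`` is a binary vector aligned with the matrix rows (1 = SL).
    Features whose positive or negative sample is empty after dropping
    missing cells are excluded with a warning.  Ties in D break by
    feature name for determinism.

    Returns a DataFrame with columns (feature, D, p_value, n_pos, n_neg).
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != matrix.shape[0]:
        raise ValueError("labels do not cover the matrix rows")
    rows = []
    for name in matrix.columns:
        col = matrix[name].to_numpy(dtype=float)
        pos = col[(y == 1) & np.isfinite(col)]
        neg = col[(y == 0) & np.isfinite(col)]
        if pos.size == 0 or neg.size == 0:
            logger.warning("feature %s: empty class sample after NA removal, skipped", name)
            continue
        d, p = ks_d_statistic(pos, neg)
        rows.append((name, d, p, int(pos.size), int(neg.size)))
    if not rows:
        raise ValueError("no feature had usable samples in both classes")
    out = pd.DataFrame(rows, columns=["feature", "D", "p_value", "n_pos", "n_neg"])
    out = out.sort_values(["D", "feature"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def write_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.6g")
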