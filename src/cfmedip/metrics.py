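"""Classification performance metrics.

Per-class one-vs-rest sensitivity, specificity, precision, accuracy and F1
from confusion counts; unweighted (macro) averages; rank-based AUROC with
mid-rank tie handling.  0/0 ratios are reported as missing, never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["class_metrics", "confusion_matrix", "per_class_metrics", "macro_average", "auroc"]


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """One-vs-rest metrics from four confusion counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); accuracy = (TP+TN)/total;
    F1 = 2TP/(2TP+FP+FN).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    return {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "precision": _safe_div(tp, tp + fp),
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
    }


def confusion_matrix(truth, predicted, labels: list) -> pd.DataFrame:
    """k x k confusion matrix (rows truth, columns predicted)."""
    truth = pd.Categorical(truth, categories=labels)
    predicted = pd.Categorical(predicted, categories=labels)
    out = pd.crosstab(truth, predicted, dropna=False)
    return out.reindex(index=labels, columns=labels, fill_value=0)


def per_class_metrics(conf: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest metrics for every class of a k x k confusion matrix."""
    total = conf.to_numpy().sum()
    rows = {}
    for cls in conf.index:
        tp = int(conf.loc[cls, cls])
        fn = int(conf.loc[cls].sum() - tp)
        fp = int(conf[cls].sum() - tp)
        tn = int(total - tp - fn - fp)
        rows[cls] = class_metrics(tp, tn, fp, fn)
    return pd.DataFrame(rows).T


def macro_average(per_class: pd.DataFrame, conf: pd.DataFrame | None = None):
    """Unweighted mean of per-class metrics plus overall accuracy.

    Missing per-class values are excluded from the mean and flagged.
    Overall accuracy is trace/total of the full matrix when provided.
    """
    if len(per_class) < 2:
        raise ValueError("macro average needs >= 2 classes")
    mean = per_class.mean(axis=0, skipna=True)
    had_missing = bool(per_class.isna().any().any())
    overall = float("nan")
    if conf is not None:
        m = conf.to_numpy()
        overall = float(np.trace(m) / m.sum())
    return mean, overall, had_missing


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``labels`` is binary (1 = positive); ties in the scores are handled by
    mid-ranks.  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))
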