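"""Binary-classifier evaluation: confusion counts, point metrics, rank AUC,
average precision, and ROC / precision-recall curves.

AUC uses the rank formula

    AUC = (sum of positive-sample ranks - M(M+1)/2) / (M * N)

with scores ranked ascending and tied scores given average ranks, which
makes the value equal the probability that a random positive outranks a
random negative (ties counting one half).  Average precision is the
step-wise sum AP = sum_n (Recall_n - Recall_{n-1}) * Precision_n over the
descending distinct-score thresholds, with Recall_0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    """The eight-metric evaluation suite plus the counts behind it."""

    TP: int
    FP: int
    FN: int
    TN: int
    PPV: float
    NPV: float
    SEN: float
    SPE: float
    ACC: float
    MCC: float
    AUC: float
    AP: float
    threshold: float = 0.5
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("TP", "FP", "FN", "TN", "PPV", "NPV", "SEN", "SPE",
                      "ACC", "MCC", "AUC", "AP", "threshold", "undefined")
        }


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return scores, labels.astype(int)


def confusion(scores, labels, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """Confusion counts (TP, FP, FN, TN); score >= threshold predicts positive."""
    scores, labels = _check_inputs(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return tp, fp, fn, tn


def point_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """PPV, NPV, SEN, SPE, ACC and MCC from confusion counts.

    A metric whose denominator is zero is reported as ``nan`` and listed
    under ``undefined``; MCC is reported as 0 (flagged) when any marginal
    is zero.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("no samples")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    acc = (tp + tn) / total
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    return {"PPV": ppv, "NPV": npv, "SEN": sen, "SPE": spe, "ACC": acc,
            "MCC": mcc, "undefined": undefined}


def auc_rank(scores, labels) -> float:
    """Rank-formula AUC with average ranks for ties."""
    scores, labels = _check_inputs(scores, labels)
    m = int(labels.sum())
    n = len(labels) - m
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # ascending, average ranks for ties
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def average_precision(scores, labels) -> float:
    """Step-wise average precision over descending distinct-score thresholds."""
    scores, labels = _check_inputs(scores, labels)
    m = int(labels.sum())
    if m == 0:
        raise ValueError("AP needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, len(scores) + 1)
    # thresholds at the last index of each distinct score
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    recall = tp_cum[distinct] / m
    precision = tp_cum[distinct] / pred_cum[distinct]
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def curves(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC and precision-recall point lists from a distinct-score sweep.

    Returns ``(roc, pr)`` where ``roc`` has rows (FPR, TPR) beginning at
    (0, 0) and ending at (1, 1), and ``pr`` has rows (Recall, Precision)
    ending at recall 1.
    """
    scores, labels = _check_inputs(scores, labels)
    m = int(labels.sum())
    n = len(labels) - m
    if m == 0 or n == 0:
        raise ValueError("curves need both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tpr = tp_cum[distinct] / m
    fpr = fp_cum[distinct] / n
    roc = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    recall = tpr
    precision = tp_cum[distinct] / (distinct + 1)
    pr = np.column_stack([recall, precision])
    return roc, pr


def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full eight-metric report for one score vector."""
    tp, fp, fn, tn = confusion(scores, labels, threshold)
    pm = point_metrics(tp, fp, fn, tn)
    return MetricsReport(
        TP=tp, FP=fp, FN=fn, TN=tn,
        PPV=pm["PPV"], NPV=pm["NPV"], SEN=pm["SEN"], SPE=pm["SPE"],
        ACC=pm["ACC"], MCC=pm["MCC"],
        AUC=auc_rank(scores, labels),
        AP=average_precision(scores, labels),
        threshold=threshold,
        undefined=pm["undefined"],
    )
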