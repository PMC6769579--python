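"""Threshold-swept classification metrics: ROC/PR curves, AUC, AUPR, top-k recall.

A pair is predicted positive when its score exceeds the threshold theta; the
sweep visits every distinct score (plus -inf so the (1, 1) ROC corner is
always reached).  AUC is the trapezoid area over the swept ROC points, which
equals the Mann-Whitney pairwise-comparison estimator with ties counted 1/2.
Precision at TP + FP = 0 is defined as 1, anchoring the PR curve at recall 0.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels.astype(np.int64)


def confusion_at(scores: np.ndarray, labels: np.ndarray, theta: float) -> dict[str, float]:
    """Confusion counts and rates at one threshold (positive iff score > theta)."""
    scores, labels = _validate(scores, labels)
    pred = scores > theta
    TP = int(np.sum(pred & (labels == 1)))
    FP = int(np.sum(pred & (labels == 0)))
    FN = int(np.sum(~pred & (labels == 1)))
    TN = int(np.sum(~pred & (labels == 0)))
    P, Nn = TP + FN, TN + FP
    return {
        "TP": TP, "FP": FP, "TN": TN, "FN": FN,
        "TPR": TP / P if P else 0.0,
        "FPR": FP / Nn if Nn else 0.0,
        "Precision": TP / (TP + FP) if TP + FP else 1.0,
        "Recall": TP / P if P else 0.0,
    }


def sweep(scores: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised threshold sweep over every distinct score and -inf.

    Returns arrays ordered by descending threshold; the first point has no
    predicted positives and the last predicts everything positive.
    """
    scores, labels = _validate(scores, labels)
    P = int(labels.sum())
    Nn = len(labels) - P
    if P == 0 or Nn == 0:
        raise ValueError("both classes must be present to sweep thresholds")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(1 - l_sorted)
    # indices of the last occurrence of each distinct score in descending order
    distinct_last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    TP = np.r_[0, cum_tp[distinct_last]].astype(np.float64)
    FP = np.r_[0, cum_fp[distinct_last]].astype(np.float64)
    thetas = np.r_[np.inf, s_sorted[distinct_last]]
    with np.errstate(invalid="ignore"):
        precision = np.where(TP + FP > 0, TP / np.maximum(TP + FP, 1), 1.0)
    return {
        "theta": thetas,
        "TP": TP, "FP": FP, "FN": P - TP, "TN": Nn - FP,
        "TPR": TP / P, "FPR": FP / Nn,
        "Precision": precision, "Recall": TP / P,
    }


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoid area under the ROC curve."""
    sw = sweep(scores, labels)
    return float(np.trapezoid(sw["TPR"], sw["FPR"]))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoid area under the precision-recall curve (anchored at recall 0)."""
    sw = sweep(scores, labels)
    return float(np.trapezoid(sw["Precision"], sw["Recall"]))


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(P*N) pairwise-comparison AUC estimator (ties count 1/2).

    Used as an independent cross-check of :func:`auc_roc`.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def topk_recall(
    rankings: Mapping[int, Sequence[int]],
    positives: Mapping[int, set[int]],
    k_values: Sequence[int],
) -> dict[int, float]:
    """Mean per-disease recall of held-out positives within the top-k candidates.

    ``rankings[j]`` is disease ``j``'s candidate list in descending score
    order; ``positives[j]`` the held-out positive candidates.  Diseases with
    no held-out positives are skipped; each ``k`` must not exceed any scored
    disease's candidate count.
    """
    diseases = [j for j, pos in positives.items() if pos]
    if not diseases:
        raise ValueError("no disease has held-out positives")
    out: dict[int, float] = {}
    for k in k_values:
        recalls = []
        for j in diseases:
            ranked = rankings[j]
            if k > len(ranked):
                raise ValueError(f"k={k} exceeds the {len(ranked)} candidates of disease {j}")
            pos = positives[j]
            hit = sum(1 for c in ranked[:k] if c in pos)
            recalls.append(hit / len(pos))
        out[k] = float(np.mean(recalls))
    return out
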