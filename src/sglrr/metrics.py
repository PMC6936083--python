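"""Clustering agreement metrics: Acc, pairwise MCC, Rand index, NMI.

Accuracy maps predicted clusters to true classes one-to-one by optimal
assignment (Kuhn-Munkres on the contingency table) before counting
matches. MCC and the Rand index are pair-counting metrics over the
n(n-1)/2 unordered sample pairs; NMI is 2 I(X;Y) / (H(X) + H(Y)) with
plug-in probabilities and base-2 logarithms. All values live on the 0-1
(MCC: -1..1) scale; callers that want the percentage convention multiply
by 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "PairCounts",
    "accuracy",
    "pair_counts",
    "mcc",
    "rand_index",
    "nmi",
    "all_metrics",
]


@dataclass
class PairCounts:
    """Unordered-pair confusion counts between two partitions.

    TP: same cluster in both; FP: different true / same predicted;
    TN: different in both; FN: same true / different predicted.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _contingency(true_labels, pred_labels) -> np.ndarray:
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.size} vs {p.size}")
    if t.size == 0:
        raise ValueError("labels must be non-empty")
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    C = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def accuracy(true_labels, pred_labels) -> float:
    """Clustering accuracy under the optimal one-to-one cluster-to-class map."""
    C = _contingency(true_labels, pred_labels)
    r, c = linear_sum_assignment(C, maximize=True)
    return float(C[r, c].sum() / C.sum())


def pair_counts(true_labels, pred_labels) -> PairCounts:
    """Classify all unordered sample pairs as TP/FP/TN/FN."""
    C = _contingency(true_labels, pred_labels)
    n = int(C.sum())
    if n < 2:
        raise ValueError("need at least 2 samples for pair counting")

    def _pairs(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    tp = _pairs(C)
    same_true = _pairs(C.sum(axis=1))
    same_pred = _pairs(C.sum(axis=0))
    fn = same_true - tp
    fp = same_pred - tp
    tn = total - tp - fn - fp
    return PairCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def mcc(counts: PairCounts) -> float:
    """Pairwise Matthews correlation coefficient; degenerate denominators -> 0."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(float(denom)))


def rand_index(true_labels, pred_labels) -> float:
    """Rand index: fraction of pairs on which the partitions agree."""
    c = pair_counts(true_labels, pred_labels)
    return float((c.TP + c.TN) / c.total)


def nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information 2 I / (H_true + H_pred), log base 2.

    Two identical single-cluster partitions score 1.0; if exactly one
    partition is a single cluster (one entropy zero) the score is 0.0.
    """
    C = _contingency(true_labels, pred_labels)
    n = C.sum()
    pt = C.sum(axis=1) / n
    pp = C.sum(axis=0) / n

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    ht, hp = _entropy(pt), _entropy(pp)
    if ht == 0.0 and hp == 0.0:
        return 1.0  # both trivial partitions, necessarily identical
    if ht == 0.0 or hp == 0.0:
        return 0.0
    pj = C / n
    mask = pj > 0
    mi = float(
        (pj[mask] * np.log2(pj[mask] / np.outer(pt, pp)[mask])).sum()
    )
    return float(2.0 * mi / (ht + hp))


def all_metrics(true_labels, pred_labels) -> dict[str, float]:
    """Acc, MCC, RI and NMI for one pair of label vectors (0-1 scale)."""
    return {
        "acc": accuracy(true_labels, pred_labels),
        "mcc": mcc(pair_counts(true_labels, pred_labels)),
        "ri": rand_index(true_labels, pred_labels),
        "nmi": nmi(true_labels, pred_labels),
    }
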