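"""Scoring inferred networks and subnetworks against a reference.

AUC is the Mann–Whitney rank statistic: the probability that a randomly
chosen true edge outscores a randomly chosen non-edge, with ties counted
half — identical to the area under the full threshold-sweep ROC curve.

Confusion metrics follow the rescale-to-100 convention: (TP, FP) are
scaled to sum to 100 and (TN, FN) likewise, after which
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and prediction
accuracy = (TP+TN)/(TP+FP+TN+FN), all reported as percentages.  Display
rounding is one decimal, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "roc_auc",
    "rescale_confusion",
    "confusion_metrics",
    "evaluate_subnetwork",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN counts (real-valued to allow the rescaling convention)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite number")
            setattr(self, name, v)


@dataclass
class ConfusionMetrics:
    """Sensitivity, specificity and prediction accuracy as percentages."""

    sensitivity: float
    specificity: float
    accuracy: float

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        """Display values, rounded half-up (matching report style)."""
        return {
            "sensitivity": round_half_up(self.sensitivity, decimals),
            "specificity": round_half_up(self.specificity, decimals),
            "accuracy": round_half_up(self.accuracy, decimals),
        }


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def roc_auc(pair_scores, reference) -> float:
    """Rank-statistic AUC of per-pair scores against a reference edge set.

    Parameters
    ----------
    pair_scores : mapping
        ``{(gene_a, gene_b): score}`` over the scored pairs (orientation
        irrelevant; pairs are canonicalized).
    reference : iterable of pairs
        The true undirected edges.  Reference pairs not present in
        ``pair_scores`` are ignored; at least one scored positive and one
        scored negative pair are required.
    """
    ref = {_canonical_pair(a, b) for a, b in reference}
    labels = []
    scores = []
    for pair, s in pair_scores.items():
        key = _canonical_pair(*pair)
        labels.append(key in ref)
        scores.append(float(s))
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC needs ≥1 positive and ≥1 negative pair (got {n_pos} and {n_neg})"
        )
    ranks = stats.rankdata(scores)  # average ranks: ties count half
    rank_sum = float(ranks[labels].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def rescale_confusion(counts: ConfusionCounts) -> ConfusionCounts:
    """Scale (TP, FP) to sum to 100 and (TN, FN) to sum to 100."""
    pos = counts.tp + counts.fp
    neg = counts.tn + counts.fn
    if pos == 0 or neg == 0:
        raise ValueError("cannot rescale: TP+FP and TN+FN must both be positive")
    return ConfusionCounts(
        tp=counts.tp / pos * 100.0,
        fp=counts.fp / pos * 100.0,
        tn=counts.tn / neg * 100.0,
        fn=counts.fn / neg * 100.0,
    )


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity and prediction accuracy (percentages).

    Unrounded values are returned; use :meth:`ConfusionMetrics.rounded`
    for one-decimal display.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: TP+FN is zero")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: TN+FP is zero")
    total = counts.tp + counts.fp + counts.tn + counts.fn
    return ConfusionMetrics(
        sensitivity=counts.tp / (counts.tp + counts.fn) * 100.0,
        specificity=counts.tn / (counts.tn + counts.fp) * 100.0,
        accuracy=(counts.tp + counts.tn) / total * 100.0,
    )


def evaluate_subnetwork(sub, positives, net, seed: int) -> ConfusionCounts:
    """Confusion counts for a subnetwork against a positive gene set.

    TP/FP are counted over the subnetwork's genes.  TN/FN come from a
    uniform random sample, of the same size as the subnetwork, drawn
    without replacement from the rest of the network (fixed ``seed``).
    The result is rescaled so each of (TP, FP) and (TN, FN) sums to 100.
    """
    positives = set(positives)
    if not positives:
        raise ValueError("positive gene set is empty")
    sub_nodes = set(sub.nodes)
    complement = sorted(net.nodes - sub_nodes)
    if len(complement) < len(sub_nodes):
        raise ValueError(
            f"network complement ({len(complement)} genes) smaller than "
            f"subnetwork ({len(sub_nodes)} genes)"
        )
    rng = np.random.default_rng(seed)
    sample = set(
        np.array(complement)[rng.choice(len(complement), size=len(sub_nodes), replace=False)]
    )
    tp = len(sub_nodes & positives)
    fp = len(sub_nodes) - tp
    fn = len(sample & positives)
    tn = len(sample) - fn
    if tp + fn == 0:
        raise ValueError("no positive gene in subnetwork or complement sample")
    return rescale_confusion(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
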