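"""ROC analysis over an ordinal 1-5 relevance-rating scale.

An AI screener that rates each citation 1 (least relevant) to 5 (most
relevant) induces five possible binary screeners — include iff rating >= t —
so its ROC is the five-point empirical curve through those operating points.
The AUC is computed as the tie-aware rank statistic: the probability that a
randomly chosen gold-positive item outranks a randomly chosen gold-negative
one, with ties credited 1/2.  On an ordinal scale this coincides exactly with
the trapezoidal area under the empirical curve (with the (0,0) and (1,1)
endpoints appended), which a property test verifies.

The operating threshold is chosen by Youden's J = sensitivity + specificity
- 1, the standard cutoff criterion when neither error is explicitly costed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import confusion, evaluate

__all__ = ["RatingVector", "RocResult", "binarize", "auc", "youden"]

logger = logging.getLogger(__name__)

SCALE = (1, 2, 3, 4, 5)


@dataclass
class RatingVector:
    """Ordinal 1-5 ratings for one rater over a corpus; ``nan`` marks missing."""

    item_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.item_ids):
            raise ValueError("values must be 1-D and aligned with item_ids")
        present = v[~np.isnan(v)]
        if present.size and (
            not np.all(present == np.round(present))
            or present.min() < 1
            or present.max() > 5
        ):
            raise ValueError("ratings must be integers in 1..5 (nan = missing)")
        self.values = v

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def complete(self) -> tuple[list[str], np.ndarray]:
        """(item_ids, int ratings) restricted to non-missing items."""
        mask = ~np.isnan(self.values)
        ids = [i for i, keep in zip(self.item_ids, mask) if keep]
        return ids, self.values[mask].astype(np.int64)


@dataclass
class RocResult:
    """Five-point ROC summary for an ordinal rater.

    ``points`` holds ``(threshold, sensitivity, 1 - specificity)`` for each
    threshold 1..5 in rising order; the (0,0)/(1,1) plotting endpoints are
    appended only by :meth:`curve_xy`.
    """

    points: list[tuple[int, float, float]]
    auc: float
    youden_j_by_threshold: dict[int, float]
    optimal_threshold: int
    optimal_j: float
    n_missing: int = 0
    ci_auc: tuple[float, float] | None = None
    _counts: dict[int, tuple[int, int, int, int]] = field(default_factory=dict, repr=False)

    def curve_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """(FPR, TPR) arrays including the (0,0) and (1,1) endpoints, for plotting."""
        fpr = np.array([1.0] + [p[2] for p in self.points] + [0.0])
        tpr = np.array([1.0] + [p[1] for p in self.points] + [0.0])
        order = np.lexsort((tpr, fpr))  # ties in FPR must rise in TPR too
        return fpr[order], tpr[order]

    def trapezoid_auc(self) -> float:
        x, y = self.curve_xy()
        return float(np.trapezoid(y, x))


def binarize(ratings: RatingVector | Sequence[float], threshold: int) -> np.ndarray:
    """Include (1) iff rating >= threshold; missing ratings propagate as nan."""
    if threshold not in SCALE:
        raise ValueError(f"threshold must be in 1..5, got {threshold}")
    v = ratings.values if isinstance(ratings, RatingVector) else np.asarray(ratings, float)
    out = np.where(v >= threshold, 1.0, 0.0)
    out[np.isnan(v)] = np.nan
    if not np.isnan(out).any():
        return out.astype(np.int64)
    return out


def _class_rating_counts(
    ratings: RatingVector | Sequence[float], gold: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-rating counts for gold positives and negatives; drops missing ratings."""
    v = ratings.values if isinstance(ratings, RatingVector) else np.asarray(ratings, float)
    g = np.asarray(gold)
    if v.shape != g.shape:
        raise ValueError("ratings and gold must be aligned")
    mask = ~np.isnan(v)
    n_missing = int((~mask).sum())
    if n_missing:
        logger.info("dropping %d items with missing ratings from ROC", n_missing)
    v, g = v[mask].astype(np.int64), g[mask]
    if not (np.any(g == 1) and np.any(g == 0)):
        raise ValueError("gold must contain both classes for ROC analysis")
    pos = np.bincount(v[g == 1], minlength=6)[1:6]
    neg = np.bincount(v[g == 0], minlength=6)[1:6]
    return pos, neg, n_missing


def auc(ratings: RatingVector | Sequence[float], gold: Sequence[int]) -> float:
    """Tie-aware AUC: P(rating of random positive > rating of random negative) + P(tie)/2."""
    pos, neg, _ = _class_rating_counts(ratings, gold)
    neg_below = np.concatenate(([0], np.cumsum(neg)[:-1]))
    favorable = np.sum(pos * (neg_below + 0.5 * neg))
    return float(favorable / (pos.sum() * neg.sum()))


def youden(ratings: RatingVector | Sequence[float], gold: Sequence[int]) -> RocResult:
    """Full ROC summary with the Youden-optimal threshold.

    J(t) is evaluated at every threshold t in 1..5; ties across thresholds
    resolve to the highest tied threshold (the more-excluding operating
    point, which maximises workload saving at equal J).
    """
    pos, neg, n_missing = _class_rating_counts(ratings, gold)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    points: list[tuple[int, float, float]] = []
    j_map: dict[int, float] = {}
    counts: dict[int, tuple[int, int, int, int]] = {}
    for t in SCALE:
        tp = int(pos[t - 1 :].sum())
        fp = int(neg[t - 1 :].sum())
        fn, tn = n_pos - tp, n_neg - fp
        sens, spec = tp / n_pos, tn / n_neg
        points.append((t, sens, 1.0 - spec))
        j_map[t] = sens + spec - 1.0
        counts[t] = (tp, fp, tn, fn)
    best_j = max(j_map.values())
    best_t = max(t for t, j in j_map.items() if j == best_j)
    return RocResult(
        points=points,
        auc=auc_from_counts(pos, neg),
        youden_j_by_threshold=j_map,
        optimal_threshold=best_t,
        optimal_j=best_j,
        n_missing=n_missing,
        _counts=counts,
    )


def auc_from_counts(pos: Sequence[int], neg: Sequence[int]) -> float:
    """Tie-aware AUC from per-rating class counts (index 0 = rating 1)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    neg_below = np.concatenate(([0], np.cumsum(neg)[:-1]))
    return float(np.sum(pos * (neg_below + 0.5 * neg)) / (pos.sum() * neg.sum()))


def roc_point_metrics(result: RocResult) -> dict[int, tuple[float, float]]:
    """(sensitivity, specificity) recomputed through the metric panel per threshold."""
    out = {}
    for t, (tp, fp, tn, fn) in result._counts.items():
        rep = evaluate(confusion([1] * tp + [0] * fn + [1] * fp + [0] * tn,
                                 [1] * (tp + fn) + [0] * (fp + tn)))
        out[t] = (rep.sensitivity, rep.specificity)
    return out
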