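"""Synthetic screening studies and exact fixtures expanded from printed counts.

Two kinds of test input are produced here.

*Exact fixtures* expand a published confusion table (or a table of cumulative
TP/FP counts per rating threshold) into an item-level dataset that reproduces
every printed count on re-tabulation.  They make desk-scale re-analysis of a
reported study possible without access to the underlying item-level data.

*Simulated studies* emulate a multi-topic abstract-screening evaluation: a
corpus with ~12% true relevance, several binary human-like raters with
specified sensitivity/specificity operating points, coupled through a shared
per-item latent "difficulty" (a one-factor probit model, so inter-rater
kappa rises with the coupling weight while each rater's marginal operating
point is preserved exactly), plus one ordinal 1-5 AI-style rater whose
rating is a thresholded class-conditional Gaussian latent score.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .consensus import DecisionMatrix
from .metrics import ConfusionCounts
from .roc_threshold import RatingVector

__all__ = [
    "RaterProfile",
    "OrdinalRaterSpec",
    "SimulationSpec",
    "fixture_from_counts",
    "ratings_fixture_from_cumulative",
    "simulate_study",
    "default_study_spec",
]


@dataclass(frozen=True)
class RaterProfile:
    """A binary rater's operating point."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class OrdinalRaterSpec:
    """Latent-score model for a 1-5 rater.

    The rating is ``1 + #{cutpoints below the item's latent score}``; the
    score is Gaussian with a class-conditional mean/sd, so the four strictly
    increasing cutpoints carve the scale into the five ratings.
    """

    name: str = "ai"
    cutpoints: tuple[float, float, float, float] = (0.09, 0.39, 1.12, 2.26)
    mean_positive: float = 1.55
    mean_negative: float = 0.0
    sd_positive: float = 0.85
    sd_negative: float = 1.0

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a simulated multi-rater screening study."""

    n_items: int
    prevalence: float
    raters: tuple[RaterProfile, ...]
    correlation: float = 0.0
    ordinal_rater: OrdinalRaterSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")


def fixture_from_counts(c: ConfusionCounts) -> pd.DataFrame:
    """Expand a confusion table into an item-level (gold, pred) table.

    Emission order is deterministic — gold descending, then prediction
    descending, then sequential ids — so the fixture is diff-stable and
    ``confusion(pred, gold)`` round-trips to ``c`` exactly.
    """
    gold = [1] * c.tp + [1] * c.fn + [0] * c.fp + [0] * c.tn
    pred = [1] * c.tp + [0] * c.fn + [1] * c.fp + [0] * c.tn
    ids = [f"item-{i:04d}" for i in range(c.n)]
    return pd.DataFrame({"id": ids, "gold": gold, "pred": pred})


def ratings_fixture_from_cumulative(
    cum: Mapping[int, tuple[int, int]], n_pos: int, n_neg: int
) -> tuple[RatingVector, np.ndarray]:
    """Expand cumulative (TP, FP) counts per rating threshold into item-level ratings.

    ``cum[t]`` gives the number of gold positives / negatives rated ``>= t``
    for thresholds in 2..5.  Per-rating class counts follow by successive
    differencing (rating-1 count = class total minus the >=2 count; a
    threshold absent from ``cum`` means no items are rated exactly at it).
    Re-thresholding the emitted items reproduces every input count.
    """
    for t in cum:
        if t not in (2, 3, 4, 5):
            raise ValueError(f"thresholds must be in 2..5, got {t}")
    full: dict[int, tuple[int, int]] = {}
    prev = (0, 0)
    for t in (5, 4, 3, 2):
        cur = cum.get(t, prev)
        if cur[0] < prev[0] or cur[1] < prev[1]:
            raise ValueError(f"cumulative counts must be non-increasing in threshold (at >={t})")
        full[t] = cur
        prev = cur
    if prev[0] > n_pos or prev[1] > n_neg:
        raise ValueError("cumulative counts exceed the class totals")
    full[1] = (n_pos, n_neg)
    pos_counts = [full[t][0] - full.get(t + 1, (0, 0))[0] for t in (1, 2, 3, 4, 5)]
    neg_counts = [full[t][1] - full.get(t + 1, (0, 0))[1] for t in (1, 2, 3, 4, 5)]

    values: list[int] = []
    gold: list[int] = []
    for rating in (5, 4, 3, 2, 1):  # rating-descending within gold-descending blocks
        values += [rating] * pos_counts[rating - 1]
        gold += [1] * pos_counts[rating - 1]
    for rating in (5, 4, 3, 2, 1):
        values += [rating] * neg_counts[rating - 1]
        gold += [0] * neg_counts[rating - 1]
    ids = [f"item-{i:04d}" for i in range(len(values))]
    return RatingVector(ids, np.array(values, float)), np.array(gold, np.int64)


def simulate_study(spec: SimulationSpec) -> tuple[DecisionMatrix, RatingVector | None]:
    """Draw one study: gold labels, correlated binary raters, ordinal AI rater.

    Gold is Bernoulli(prevalence).  Each binary rater includes item *i* iff

        sqrt(rho) * u_i + sqrt(1 - rho) * e_ir  <  Phi^{-1}(p_r)

    where ``u_i`` is the shared standard-normal item difficulty, ``rho`` is
    ``spec.correlation``, and ``p_r`` is the rater's class-conditional
    inclusion probability (sensitivity on positives, 1 - specificity on
    negatives).  The probit threshold preserves each marginal operating
    point exactly for every coupling weight.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_items
    gold = (rng.random(n) < spec.prevalence).astype(np.int64)
    u = rng.standard_normal(n)
    rho = spec.correlation

    decisions = np.empty((n, len(spec.raters)), dtype=np.int64)
    for j, rater in enumerate(spec.raters):
        p_include = np.where(gold == 1, rater.sensitivity, 1.0 - rater.specificity)
        z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        decisions[:, j] = (z < norm.ppf(p_include)).astype(np.int64)

    item_ids = [f"sim-{i:05d}" for i in range(n)]
    matrix = DecisionMatrix(
        item_ids=item_ids,
        rater_names=[r.name for r in spec.raters],
        decisions=decisions,
        gold=gold,
    )

    ratings = None
    if spec.ordinal_rater is not None:
        o = spec.ordinal_rater
        mu = np.where(gold == 1, o.mean_positive, o.mean_negative)
        sd = np.where(gold == 1, o.sd_positive, o.sd_negative)
        latent = mu + sd * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * rng.standard_normal(n))
        values = 1 + np.sum(latent[:, None] > np.asarray(o.cutpoints)[None, :], axis=1)
        ratings = RatingVector(item_ids, values.astype(float))
    return matrix, ratings


def default_study_spec(seed: int = 0) -> SimulationSpec:
    """A study spec shaped like a six-topic radiology screening evaluation.

    1198 items at 148/1198 ~ 12.4% relevance prevalence; three GP-like
    raters at published operating points, two near-concordant expert-like
    raters, moderate shared-difficulty coupling, and an ordinal AI-style
    rater whose thresholded operating points approximate the published
    cumulative confusion counts.
    """
    return SimulationSpec(
        n_items=1198,
        prevalence=148 / 1198,
        raters=(
            RaterProfile("gp1", 0.55, 0.94),
            RaterProfile("gp2", 0.55, 0.99),
            RaterProfile("gp3", 0.74, 0.94),
            RaterProfile("expert1", 0.88, 0.98),
            RaterProfile("expert2", 0.90, 0.985),
        ),
        correlation=0.5,
        ordinal_rater=OrdinalRaterSpec(),
        seed=seed,
    )
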