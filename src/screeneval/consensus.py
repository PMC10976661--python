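"""Multi-rater consensus rules and third-expert adjudication.

Screening panels combine independent include/exclude calls in three standard
ways: a *sensitive* consensus includes a citation if any rater includes it,
a *specific* consensus only if all raters do, and a *voting* consensus on a
strict majority.  The gold standard itself comes from two experts whose
disagreements are settled by a third (adjudication).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import as_binary_vector

__all__ = ["DecisionMatrix", "consensus", "adjudicate", "CONSENSUS_RULES"]

logger = logging.getLogger(__name__)

CONSENSUS_RULES = ("sensitive", "specific", "voting")

#: sentinel for a masked (missing) decision inside a DecisionMatrix
MASKED = -1


@dataclass
class DecisionMatrix:
    """Items x raters binary include/exclude decisions, optionally with gold.

    ``decisions[i, r]`` is 1 (include), 0 (exclude) or ``MASKED`` (-1) for a
    missing decision.  ``gold``, when present, is aligned to ``item_ids``.
    """

    item_ids: list[str]
    rater_names: list[str]
    decisions: np.ndarray
    gold: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.decisions, dtype=np.int64)
        if d.ndim != 2 or d.shape != (len(self.item_ids), len(self.rater_names)):
            raise ValueError(
                f"decisions shape {d.shape} does not match "
                f"{len(self.item_ids)} items x {len(self.rater_names)} raters"
            )
        if d.size and not np.all(np.isin(d, (0, 1, MASKED))):
            raise ValueError("decisions must be 0, 1, or -1 (masked)")
        self.decisions = d
        if self.gold is not None:
            self.gold = as_binary_vector(self.gold, "gold")
            if self.gold.size != len(self.item_ids):
                raise ValueError("gold must be aligned to item_ids")

    def column(self, rater: str) -> np.ndarray:
        return self.decisions[:, self.rater_names.index(rater)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.decisions, index=self.item_ids, columns=self.rater_names)
        if self.gold is not None:
            df.insert(0, "gold", self.gold)
        return df

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DecisionMatrix":
        """Build from a long-format table with columns ``id, rater, decision``."""
        wide = df.pivot(index="id", columns="rater", values="decision")
        wide = wide.fillna(MASKED).astype(np.int64)
        return cls(
            item_ids=[str(i) for i in wide.index],
            rater_names=[str(c) for c in wide.columns],
            decisions=wide.to_numpy(),
        )


def consensus(matrix: DecisionMatrix, rule: str) -> np.ndarray:
    """Combine the raters of a DecisionMatrix under one consensus rule.

    Returns a float vector: 1.0 include, 0.0 exclude, ``nan`` for items with
    any masked decision (dropped from consensus, count logged, never treated
    as an exclude vote).  For voting with an even rater count an exact tie
    resolves to include, since screening errs toward sensitivity.
    """
    if rule not in CONSENSUS_RULES:
        raise ValueError(f"rule must be one of {CONSENSUS_RULES}, got {rule!r}")
    if len(matrix.rater_names) < 2:
        raise ValueError("consensus requires at least 2 raters")
    d = matrix.decisions
    masked = np.any(d == MASKED, axis=1)
    if masked.any():
        logger.info("consensus: dropping %d items with masked decisions", masked.sum())
    if rule == "sensitive":
        out = np.any(d == 1, axis=1)
    elif rule == "specific":
        out = np.all(d == 1, axis=1)
    else:  # voting: strict majority, ties -> include
        n_raters = d.shape[1]
        out = d.sum(axis=1) * 2 >= n_raters
    result = out.astype(float)
    result[masked] = np.nan
    return result


def adjudicate(
    expert_a: Sequence[int],
    expert_b: Sequence[int],
    tiebreaker: Sequence[float],
) -> tuple[np.ndarray, int]:
    """Resolve two experts' decisions into a gold standard via a third expert.

    Where the experts agree, the shared value stands; where they disagree,
    the tiebreaker's decision is final.  The tiebreaker vector may be nan
    outside the disagreement set, but a nan at a disagreement position is a
    data error.  Returns ``(gold, n_disagreements)``.
    """
    a = as_binary_vector(expert_a, "expert_a")
    b = as_binary_vector(expert_b, "expert_b")
    t = np.asarray(tiebreaker, dtype=float)
    if not (a.shape == b.shape == t.shape):
        raise ValueError("expert and tiebreaker vectors must be aligned")
    disagree = a != b
    n_disagreements = int(disagree.sum())
    if np.isnan(t[disagree]).any():
        missing = int(np.isnan(t[disagree]).sum())
        raise ValueError(f"tiebreaker undefined at {missing} disagreement positions")
    if disagree.any() and not np.all(np.isin(t[disagree], (0, 1))):
        raise ValueError("tiebreaker decisions must be binary on the disagreement set")
    gold = a.copy()
    gold[disagree] = t[disagree].astype(np.int64)
    return gold, n_disagreements
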