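"""Confusion counts, the 11-metric diagnostic panel, and Cohen's kappa.

Every downstream quantity in the package — consensus comparisons, ROC points,
bootstrap replicates — reduces to a 2x2 confusion table against a gold
standard, so :class:`ConfusionCounts` is the atom here.  The panel covers the
standard screening metrics: sensitivity, specificity, PPV, NPV, positive and
negative likelihood ratios, balanced accuracy, Jaccard index (IoU), false
negative rate, proportion missed (FN among predicted-irrelevant, i.e.
``1 - NPV``), and workload saving (``TN / N``, the share of the corpus a
reviewer never has to read because it was correctly auto-excluded).

Undefined ratios follow a documented sentinel convention: ``0/0`` is reported
as ``nan``; a positive numerator over a zero denominator is ``inf`` (the
positive likelihood ratio of a perfectly specific rater renders as the
infinity symbol in tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import as_binary_vector, round_half_up

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "KappaResult",
    "METRIC_NAMES",
    "confusion",
    "evaluate",
    "kappa",
]

#: Panel metrics in the order screening reports print them.
METRIC_NAMES: tuple[str, ...] = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "plr",
    "nlr",
    "balanced_accuracy",
    "jaccard",
    "fnr",
    "proportion_missed",
    "workload_saving",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts against a gold standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        """Gold-positive items."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Gold-negative items."""
        return self.tn + self.fp

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


def confusion(pred: Sequence[int], gold: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate a binary prediction vector against the gold standard.

    Both vectors must be aligned, the same length, and strictly binary
    (0 = exclude, 1 = include).
    """
    p = as_binary_vector(pred, "pred")
    g = as_binary_vector(gold, "gold")
    if p.shape != g.shape:
        raise ValueError(f"length mismatch: pred has {p.size}, gold has {g.size}")
    tp = int(np.sum((p == 1) & (g == 1)))
    fp = int(np.sum((p == 1) & (g == 0)))
    tn = int(np.sum((p == 0) & (g == 0)))
    fn = int(np.sum((p == 0) & (g == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    """num/den with the sentinel convention: 0/0 -> nan, x/0 -> inf for x>0."""
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


@dataclass
class MetricReport:
    """The 11-metric panel for one rater, with optional bootstrap CIs.

    ``cis`` maps metric name to a ``(low, high)`` pair when bootstrap
    intervals have been attached; ``counts`` keeps the underlying confusion
    table so rendered rows can always be traced back to raw counts.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    balanced_accuracy: float
    jaccard: float
    fnr: float
    proportion_missed: float
    workload_saving: float
    counts: ConfusionCounts | None = None
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def value(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Panel values rounded half-up, the convention printed reports use."""
        return {k: round_half_up(v, ndigits) for k, v in self.to_dict().items()}


def evaluate(c: ConfusionCounts) -> MetricReport:
    """Compute the full metric panel from a confusion table.

    Raises ``ValueError`` on an empty table.  Identities that hold whenever
    denominators are positive: ``fnr = 1 - sensitivity``,
    ``proportion_missed = 1 - npv``, and
    ``balanced_accuracy = (sensitivity + specificity) / 2``.
    """
    if c.n == 0:
        raise ValueError("cannot evaluate metrics on an empty confusion table")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        plr=_ratio(sens, 1.0 - spec) if not math.isnan(spec) else math.nan,
        nlr=_ratio(1.0 - sens, spec) if not math.isnan(sens) else math.nan,
        balanced_accuracy=(sens + spec) / 2.0,
        jaccard=_ratio(c.tp, c.tp + c.fp + c.fn),
        fnr=_ratio(c.fn, c.tp + c.fn),
        proportion_missed=_ratio(c.fn, c.fn + c.tn),
        workload_saving=c.tn / c.n,
        counts=c,
    )


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with an optional bootstrap CI; nan when chance agreement is 1."""

    kappa: float
    ci: tuple[float, float] | None = None


def kappa(a: Sequence[int], b: Sequence[int]) -> KappaResult:
    """Cohen's kappa between two aligned binary raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` where ``p_o`` is the observed
    agreement rate and ``p_e`` the agreement expected from the two raters'
    marginal inclusion rates.  Symmetric in its arguments and invariant to
    simultaneously relabelling 0 and 1 in both vectors.  When both raters are
    constant and identical, chance agreement is 1 and kappa is undefined;
    the sentinel ``nan`` is returned rather than raising.
    """
    va = as_binary_vector(a, "a")
    vb = as_binary_vector(b, "b")
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: a has {va.size}, b has {vb.size}")
    if va.size == 0:
        raise ValueError("kappa requires at least one item")
    p_o = float(np.mean(va == vb))
    pa = float(np.mean(va))
    pb = float(np.mean(vb))
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    if p_e == 1.0:
        return KappaResult(math.nan)
    return KappaResult((p_o - p_e) / (1.0 - p_e))


def mean_kappa_against(
    target: Sequence[int], others: Mapping[str, Sequence[int]]
) -> float:
    """Mean kappa between one rater and each rater in ``others``.

    This is the summary reported as a rater's "average agreement" with the
    rest of the panel (e.g. an AI rater versus all five human raters).
    """
    if not others:
        raise ValueError("need at least one comparison rater")
    values = [kappa(target, v).kappa for v in others.values()]
    return float(np.mean(values))
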