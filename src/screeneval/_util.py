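"""Small shared helpers: binary-vector validation and half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import math

import numpy as np


def as_binary_vector(x: Sequence[int], name: str = "vector") -> np.ndarray:
    """Coerce to a 1-D int array of {0, 1}; reject anything else."""
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if arr.size and not np.all(np.isin(arr, (0, 1))):
        bad = arr[~np.isin(arr, (0, 1))][:3]
        raise ValueError(f"{name} must be binary (0/1); found values {bad.tolist()}")
    return arr.astype(np.int64)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention printed tables use.

    Python's builtin ``round`` is banker's rounding; reports here follow
    half-up so e.g. 0.125 -> 0.13 at two decimals.  inf/nan pass through.
    """
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
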