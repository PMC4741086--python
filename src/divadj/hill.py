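"""Empirical Hill numbers and empirical diversity profiles.

The Hill number of order ``q`` for relative abundances ``p_i`` is

    qD = (sum_i p_i^q)^(1/(1-q)),   q >= 0, q != 1,

with the ``q -> 1`` limit ``exp(-sum_i p_i log p_i)`` (exponential Shannon
entropy).  ``qD`` is the *effective number of taxa*: the number of equally
abundant taxa that would give the same diversity value.  ``q = 0`` is
richness, ``q = 2`` inverse Simpson concentration; larger ``q`` discounts
rare taxa more strongly.

The empirical (plug-in) versions substitute the observed proportions
``X_i/n``.  Sums run over the sparse frequency representation,
``sum_k f_k (k/n)^q`` — never over expanded taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientDataError
from .freq_data import FrequencyCounts

__all__ = ["ProfilePoint", "hill_empirical", "profile_empirical", "default_q_grid"]

#: Orders q with |q - 1| below this use the dedicated entropy branch.
_Q1_EPS = 1e-6


@dataclass(frozen=True)
class ProfilePoint:
    """One point of a diversity profile: order, value, optional uncertainty."""

    q: float
    value: float
    kind: str = "empirical"  # or "asymptotic"
    se: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")


def default_q_grid(q_max: float = 3.0, step: float = 0.05) -> np.ndarray:
    """Default profile grid: 0 to ``q_max`` in steps of ``step``."""
    return np.round(np.arange(0.0, q_max + step / 2, step), 10)


def hill_empirical(fc: FrequencyCounts, q: float) -> float:
    """Plug-in Hill number of order ``q >= 0`` from frequency counts."""
    if q < 0:
        raise InsufficientDataError(f"diversity order must be >= 0, got q={q}")
    n = fc.n
    if n < 1:
        raise InsufficientDataError("empty sample has undefined diversity")
    ks, fs = fc.arrays()
    p = ks / n
    if abs(q - 1.0) < _Q1_EPS:
        return float(np.exp(-np.sum(fs * p * np.log(p))))
    if q == 0:
        return float(fc.s_obs)
    return float(np.sum(fs * p**q) ** (1.0 / (1.0 - q)))


def profile_empirical(
    fc: FrequencyCounts, q_grid: Sequence[float] | Iterable[float] | None = None
) -> list[ProfilePoint]:
    """Empirical diversity profile over ``q_grid`` (default 0..3 step 0.05)."""
    grid = default_q_grid() if q_grid is None else np.asarray(list(q_grid), dtype=float)
    if grid.size == 0:
        raise InsufficientDataError("q grid is empty")
    return [ProfilePoint(q=float(q), value=hill_empirical(fc, float(q))) for q in grid]
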