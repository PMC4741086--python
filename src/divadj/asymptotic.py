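"""Asymptotic (undetected-taxa-corrected) Hill-number diversity profiles.

The empirical profile underestimates true diversity because samples miss
taxa.  The asymptotic estimator corrects this using only the sample's
frequency counts.  Writing ``f1`` for the singleton value in force (the
estimated count on adjusted data) and

    A = 2 f_2 / [(n-1) f1 + 2 f_2]            (f_2 > 0)
      = 2 / [(n-1)(f1 - 1) + 2]               (f_2 = 0, f1 != 0)
      = 1                                     (f_2 = f1 = 0),

the estimator of order ``q`` is

    qD_hat = [ sum_{k=0}^{n-1} C(q-1, k) (-1)^k Delta(k)
               + (f1/n) (1-A)^{-(n-1)} ( A^{q-1}
                 - sum_{r=0}^{n-1} C(q-1, r) (A-1)^r ) ]^{1/(1-q)},

where ``Delta(0) = 1`` and
``Delta(k) = sum_j [C(n-k-1, j-1) / C(n, j)] f_j`` for ``j <= n-k``.

Three special cases are evaluated by their own closed forms: ``q = 0``
reduces analytically to the adjusted Chao1 estimator; ``q = 1`` to a
low-bias exponential-Shannon-entropy estimator; ``q = 2`` to the inverse of
the unbiased Simpson sum ``sum_i X_i (X_i - 1) / [n (n-1)]`` (the singleton
slot does not enter the ``q = 2`` sum, only the adjusted ``n`` does).

Numerics: binomial ratios go through log-gamma; ``(1-A)^{-(n-1)}`` is
``exp(-(n-1) log1p(-A))`` (raw powering overflows for small ``A`` and large
``n``); the generalized binomial coefficients use the ratio recurrence
``b_k = b_{k-1} (k - q) / k`` with ``b_0 = 1`` for ``b_k = (-1)^k C(q-1, k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import digamma, gammaln

from .exceptions import InsufficientDataError
from .freq_data import AdjustedSample, FrequencyCounts, as_sample
from .hill import ProfilePoint, default_q_grid
from .richness import chao1_adjusted

__all__ = [
    "AsymptoticComponents",
    "components",
    "diversity_asymptotic",
    "shannon_asymptotic",
    "simpson_asymptotic",
    "profile_asymptotic",
]

_EULER_GAMMA = 0.5772156649015328606
_Q1_EPS = 1e-6


@dataclass(frozen=True)
class AsymptoticComponents:
    """Pieces of the profile estimator: ``A``, the ``Delta(k)`` array, ``f1``."""

    A: float
    delta: np.ndarray  # Delta(k), k = 0 .. n-1
    f1_used: float


def _dominance_parameter(n: int, f1: float, f2: float) -> float:
    if f2 > 0:
        return 2 * f2 / ((n - 1) * f1 + 2 * f2)
    if f1 > 0:
        return 2 / ((n - 1) * (f1 - 1) + 2)
    return 1.0


def _delta_array(fc: FrequencyCounts, n: int) -> np.ndarray:
    """``Delta(k)`` for k = 0..n-1, accumulated in log space per multiplicity."""
    delta = np.zeros(n)
    for j, fj in fc.counts.items():
        if j > n:
            continue
        k = np.arange(0, n - j + 1)
        # log C(n-k-1, j-1) - log C(n, j)
        log_num = gammaln(n - k) - gammaln(j) - gammaln(n - k - j + 1)
        log_den = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        delta[: n - j + 1] += fj * np.exp(log_num - log_den)
    delta[0] = 1.0  # exact by construction: sum_j f_j (j/n) = 1
    return delta


def components(sample: AdjustedSample | FrequencyCounts) -> AsymptoticComponents:
    """Compute ``A`` and the ``Delta(k)`` sequence for a sample."""
    sample = as_sample(sample)
    n = sample.n_adjusted
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got n={n}")
    f1 = float(sample.f1_hat)
    a = _dominance_parameter(n, f1, sample.adjusted.f(2))
    return AsymptoticComponents(A=a, delta=_delta_array(sample.adjusted, n), f1_used=f1)


def _binom_series_coeffs(q: float, n: int) -> np.ndarray:
    """``b_k = (-1)^k C(q-1, k)`` for k = 0..n-1 via the ratio recurrence."""
    k = np.arange(1, n)
    return np.concatenate(([1.0], np.cumprod((k - q) / k)))


def _general_sum(sample: AdjustedSample, q: float, comp: AsymptoticComponents) -> float:
    """The bracketed quantity of the profile estimator (before the 1/(1-q) power)."""
    n = sample.n_adjusted
    a, f1 = comp.A, comp.f1_used
    b = _binom_series_coeffs(q, n)
    main = float(np.sum(b * comp.delta))
    tail = 0.0
    if f1 > 0 and a < 1.0:
        x = 1.0 - a
        series = float(np.sum(b * np.power(x, np.arange(n))))
        pw = math.exp(-(n - 1) * math.log1p(-a))
        tail = f1 / n * pw * (a ** (q - 1.0) - series)
    return main + tail


def shannon_asymptotic(sample: AdjustedSample | FrequencyCounts) -> float:
    """Low-bias exponential Shannon entropy (the ``q = 1`` special case).

    ``exp( sum_j f_j (j/n) [H_{n-1} - H_{j-1}]
          + (f1/n)(1-A)^{-(n-1)} [-log A - sum_{r=1}^{n-1} (1-A)^r / r] )``
    with harmonic numbers ``H_m``.
    """
    sample = as_sample(sample)
    fc = sample.adjusted
    n = sample.n_adjusted
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got n={n}")

    def harm(m: np.ndarray | int) -> np.ndarray | float:
        return digamma(np.asarray(m, dtype=float) + 1.0) + _EULER_GAMMA

    ks, fs = fc.arrays()
    mask = ks <= n - 1
    ks, fs = ks[mask], fs[mask]
    h = float(np.sum(fs * (ks / n) * (harm(n - 1) - harm(ks - 1))))

    f1 = float(sample.f1_hat)
    a = _dominance_parameter(n, f1, fc.f(2))
    if f1 > 0 and a < 1.0:
        r = np.arange(1, n)
        series = float(np.sum(np.power(1.0 - a, r) / r))
        pw = math.exp(-(n - 1) * math.log1p(-a))
        h += f1 / n * pw * (-math.log(a) - series)
    return math.exp(h)


def simpson_asymptotic(sample: AdjustedSample | FrequencyCounts) -> float:
    """Nearly unbiased inverse Simpson diversity (the ``q = 2`` special case)."""
    sample = as_sample(sample)
    fc = sample.adjusted
    n = sample.n_adjusted
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got n={n}")
    ks, fs = fc.arrays()
    s = float(np.sum(fs * ks * (ks - 1))) / (n * (n - 1))
    if s == 0:
        return math.inf
    return 1.0 / s


def diversity_asymptotic(
    sample: AdjustedSample | FrequencyCounts,
    q: float,
    _comp: AsymptoticComponents | None = None,
    use_special_cases: bool = True,
) -> ProfilePoint:
    """Asymptotic Hill number of order ``q`` for one sample.

    ``use_special_cases=False`` forces the general alternating series even
    at q = 0, 1, 2 (useful for verifying the analytic reductions).
    """
    if q < 0:
        raise InsufficientDataError(f"diversity order must be >= 0, got q={q}")
    sample = as_sample(sample)
    if use_special_cases:
        if q == 0:
            return ProfilePoint(q=0.0, value=chao1_adjusted(sample).estimate, kind="asymptotic")
        if abs(q - 1.0) < _Q1_EPS:
            return ProfilePoint(q=float(q), value=shannon_asymptotic(sample), kind="asymptotic")
        if q == 2:
            return ProfilePoint(q=2.0, value=simpson_asymptotic(sample), kind="asymptotic")
    comp = _comp if _comp is not None else components(sample)
    if abs(q - 1.0) < _Q1_EPS:
        # the bracket -> 1 and the exponent diverges at q = 1; use the limit
        return ProfilePoint(q=float(q), value=shannon_asymptotic(sample), kind="asymptotic")
    total = _general_sum(sample, q, comp)
    if not math.isfinite(total) or total <= 0:
        raise ArithmeticError(
            f"asymptotic series failed at q={q}: bracket={total!r}"
        )
    return ProfilePoint(q=float(q), value=float(total ** (1.0 / (1.0 - q))), kind="asymptotic")


def profile_asymptotic(
    sample: AdjustedSample | FrequencyCounts,
    q_grid: Sequence[float] | Iterable[float] | None = None,
) -> list[ProfilePoint]:
    """Asymptotic diversity profile over ``q_grid`` (default 0..3 step 0.05)."""
    sample = as_sample(sample)
    grid = default_q_grid() if q_grid is None else np.asarray(list(q_grid), dtype=float)
    if grid.size == 0:
        raise InsufficientDataError("q grid is empty")
    comp = components(sample)
    return [diversity_asymptotic(sample, float(q), _comp=comp) for q in grid]
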