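"""Sample coverage, completeness curves, and rarefaction/extrapolation.

*Sample coverage* is the fraction of individuals in the community that
belong to taxa already observed in the sample — Turing's measure of sample
completeness, estimable from the data themselves:

    C_hat(n) = 1 - (f_1/n) * [(n-1) f_1 / ((n-1) f_1 + 2 f_2)].

Two standardizations make diversity comparable across samples: matching
sample *size* m (rarefaction for m < n, extrapolation for m > n) or
matching *coverage*.  Both are provided for q = 0, 1, 2, together with the
sample-completeness curve that bridges them.  When an adjusted sample is
supplied, every formula uses the adjusted counts and adjusted n throughout.

Interpolation/extrapolation formulas (the standard size-based framework,
pinned by their boundary behavior — each curve is continuous at m = n and
the q = 1, 2 curves converge to the asymptotic estimates as m grows):

- q = 0 rarefaction is the exact hypergeometric expectation
  ``S(m) = sum_k f_k [1 - C(n-k, m) / C(n, m)]``; extrapolation is
  ``S_obs + f0_hat [1 - (1 - f_1/(n f0_hat + f_1))^{m-n}]`` with ``f0_hat``
  the Chao1 undetected-richness term.
- q = 1 rarefaction exponentiates the entropy of the expected rarefied
  counts ``E[f_k(m)] = sum_j f_j C(j,k) C(n-j, m-k) / C(n,m)``;
  extrapolation blends the empirical and asymptotic entropies with weights
  ``n/(n+m*)`` and ``m*/(n+m*)``.
- q = 2 has the closed form ``1 / [1/m + ((m-1)/m) sum_i X_i(X_i-1)/(n(n-1))]``
  for every m.

Binomial coefficient ratios are evaluated as telescoping products or in
log space — never via raw factorials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln

from .exceptions import (
    InsufficientDataError,
    UnreachableCoverageError,
    UnsupportedOrderError,
)
from .freq_data import AdjustedSample, FrequencyCounts, as_sample
from .asymptotic import shannon_asymptotic
from .hill import hill_empirical

__all__ = [
    "RECurvePoint",
    "CompletenessPoint",
    "coverage_at_n",
    "coverage_at_m",
    "rarefy_extrapolate",
    "coverage_based_curve",
    "completeness_curve",
    "invert_coverage",
    "default_size_grid",
]


@dataclass(frozen=True)
class RECurvePoint:
    """One point of a rarefaction/extrapolation curve."""

    m: int
    coverage: float
    q: float
    value: float
    segment: str  # interpolated | observed | extrapolated
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")


class CompletenessPoint(NamedTuple):
    m: int
    coverage: float
    segment: str


def _segment(m: int, n: int) -> str:
    return "observed" if m == n else ("interpolated" if m < n else "extrapolated")


def _log_binom(a, b):
    """log C(a, b); caller guarantees 0 <= b <= a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _subsample_ratios(n: int, m: int, kmax: int, offset: int = 0) -> np.ndarray:
    """``C(n - k, m) / C(n - offset, m)`` for k = offset..kmax, as exact
    telescoping products ``prod (n - m - i + 1)/(n - i + 1)`` (more accurate
    than differencing large log-gamma values)."""
    ratios = np.zeros(kmax - offset + 1)
    acc = 1.0
    for k in range(offset, kmax + 1):
        if k > offset:
            acc = acc * (n - m - k + 1) / (n - k + 1) if k <= n - m else 0.0
        ratios[k - offset] = acc
    return ratios


def _counts(sample: AdjustedSample) -> tuple[FrequencyCounts, int]:
    return sample.adjusted, sample.n_adjusted


def coverage_at_n(data: FrequencyCounts | AdjustedSample) -> float:
    """Estimated coverage of the sample at its own size."""
    fc, n = _counts(as_sample(data))
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for coverage, got n={n}")
    f1, f2 = fc.f(1), fc.f(2)
    if f1 == 0:
        return 1.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


def coverage_at_m(data: FrequencyCounts | AdjustedSample, m: int) -> float:
    """Expected coverage of a sample rarefied or extrapolated to size ``m``.

    Rarefaction (m < n): ``1 - sum_k f_k (k/n) C(n-k, m) / C(n-1, m)``.
    Extrapolation (m = n + m*): the geometric decay
    ``1 - (f_1/n) [(n-1) f_1 / ((n-1) f_1 + 2 f_2)]^{m*+1}``.
    """
    sample = as_sample(data)
    fc, n = _counts(sample)
    if m < 1:
        raise InsufficientDataError(f"sample size must be >= 1, got m={m}")
    if m == n:
        return coverage_at_n(sample)
    f1, f2 = fc.f(1), fc.f(2)
    if m > n:
        if f1 == 0:
            return 1.0
        ratio = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
        return 1.0 - (f1 / n) * ratio ** (m - n + 1)
    ks, fs = fc.arrays()
    mask = ks <= n - m  # C(n-k, m) = 0 otherwise
    ks_, fs_ = ks[mask], fs[mask]
    if ks_.size == 0:
        return 1.0
    ratios = _subsample_ratios(n, m, int(ks_.max()), offset=1)  # vs C(n-1, m)
    return float(1.0 - np.sum(fs_ * (ks_ / n) * ratios[ks_ - 1]))


def default_size_grid(n: int, max_size: int | None = None, knots: int = 40) -> np.ndarray:
    """Integer size grid from 1 to ``max_size`` (default 2n), always containing n."""
    max_size = 2 * n if max_size is None else int(max_size)
    grid = np.unique(np.round(np.linspace(1, max_size, knots)).astype(int))
    if n <= max_size:
        grid = np.unique(np.concatenate([grid, [n]]))
    return grid


def _richness_at_m(fc: FrequencyCounts, n: int, m: int) -> float:
    if m >= n:
        f1, f2 = fc.f(1), fc.f(2)
        a = (n - 1) / n
        f0_hat = a * f1 * f1 / (2 * f2) if f2 > 0 else a * f1 * (f1 - 1) / 2
        if f0_hat <= 0 or f1 == 0:
            return float(fc.s_obs)
        mstar = m - n
        return fc.s_obs + f0_hat * (1.0 - (1.0 - f1 / (n * f0_hat + f1)) ** mstar)
    ks, fs = fc.arrays()
    mask = ks <= n - m
    ks_, fs_ = ks[mask], fs[mask]
    seen = float(np.sum(fs))
    if ks_.size:
        ratios = _subsample_ratios(n, m, int(ks_.max()))
        seen -= float(np.sum(fs_ * ratios[ks_]))
    return seen


def _entropy_interpolated(fc: FrequencyCounts, n: int, m: int) -> float:
    """Entropy of the expected rarefied frequency counts at m <= n."""
    ks, fs = fc.arrays()
    log_cnm = _log_binom(n, m)
    h = 0.0
    for k in range(1, min(m, int(ks.max())) + 1):
        mask = (ks >= k) & (m - k <= n - ks)
        j, fj = ks[mask], fs[mask]
        if j.size == 0:
            continue
        efk = float(np.sum(fj * np.exp(_log_binom(j, k) + _log_binom(n - j, m - k) - log_cnm)))
        h += (k / m) * math.log(m / k) * efk
    return h


def _shannon_at_m(sample: AdjustedSample, fc: FrequencyCounts, n: int, m: int) -> float:
    if m < n:
        return math.exp(_entropy_interpolated(fc, n, m))
    if m == n:
        return hill_empirical(fc, 1.0)
    h_emp = math.log(hill_empirical(fc, 1.0))
    h_asy = math.log(shannon_asymptotic(sample))
    mstar = m - n
    return math.exp(n / (n + mstar) * h_emp + mstar / (n + mstar) * h_asy)


def _simpson_at_m(fc: FrequencyCounts, n: int, m: int) -> float:
    ks, fs = fc.arrays()
    s = float(np.sum(fs * ks * (ks - 1))) / (n * (n - 1))
    denom = 1.0 / m + (m - 1) / m * s
    return 1.0 / denom if denom > 0 else math.inf


def rarefy_extrapolate(
    data: FrequencyCounts | AdjustedSample,
    q: int,
    m_grid: Sequence[int] | Iterable[int] | None = None,
) -> list[RECurvePoint]:
    """Sample-size-based rarefaction/extrapolation curve for ``q`` in {0, 1, 2}."""
    if q not in (0, 1, 2):
        raise UnsupportedOrderError(f"size-based curves support q in {{0, 1, 2}}, got {q}")
    sample = as_sample(data)
    fc, n = _counts(sample)
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got n={n}")
    grid = default_size_grid(n) if m_grid is None else [int(m) for m in m_grid]
    points = []
    for m in grid:
        if m < 1:
            raise InsufficientDataError(f"sample size must be >= 1, got m={m}")
        if q == 0:
            value = _richness_at_m(fc, n, m)
        elif q == 1:
            value = _shannon_at_m(sample, fc, n, m)
        else:
            value = _simpson_at_m(fc, n, m)
        points.append(
            RECurvePoint(
                m=int(m),
                coverage=coverage_at_m(sample, int(m)),
                q=float(q),
                value=float(value),
                segment=_segment(int(m), n),
            )
        )
    return points


def invert_coverage(data: FrequencyCounts | AdjustedSample, target: float) -> int:
    """Smallest sample size whose expected coverage reaches ``target``.

    Rarefaction targets are found by integer bisection on the monotone
    ``C_hat(m)``; extrapolation targets use the closed-form geometric decay,
    ``m* = ceil(log(deficit ratio) / log(ratio)) - 1``.
    """
    sample = as_sample(data)
    fc, n = _counts(sample)
    if not (0.0 < target < 1.0):
        raise UnreachableCoverageError(f"target coverage must be in (0, 1), got {target}")
    c_n = coverage_at_n(sample)
    if target <= c_n:
        lo, hi = 1, n
        if coverage_at_m(sample, 1) >= target:
            return 1
        while hi - lo > 1:  # C(lo) < target <= C(hi)
            mid = (lo + hi) // 2
            if coverage_at_m(sample, mid) >= target:
                hi = mid
            else:
                lo = mid
        return hi
    f1, f2 = fc.f(1), fc.f(2)
    if f1 == 0:
        return n  # coverage already 1 at the observed size
    ratio = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    if ratio >= 1.0:
        raise UnreachableCoverageError(
            f"coverage cannot exceed {1 - f1 / n:.6f} by extrapolation (f2 = 0)"
        )
    deficit = (1.0 - target) * n / f1
    mstar = max(math.ceil(math.log(deficit) / math.log(ratio)) - 1, 0)
    # guard against the ceiling landing one step short
    while coverage_at_m(sample, n + mstar) < target:
        mstar += 1
    return n + mstar


def coverage_based_curve(
    data: FrequencyCounts | AdjustedSample,
    q: int,
    coverage_grid: Sequence[float] | Iterable[float],
) -> list[RECurvePoint]:
    """Coverage-based curve: each target coverage inverted to a size, then evaluated."""
    sample = as_sample(data)
    points = []
    for target in coverage_grid:
        m = invert_coverage(sample, float(target))
        (pt,) = rarefy_extrapolate(sample, q, [m])
        points.append(pt)
    return points


def completeness_curve(
    data: FrequencyCounts | AdjustedSample,
    m_grid: Sequence[int] | Iterable[int] | None = None,
) -> list[CompletenessPoint]:
    """Sample-completeness curve: coverage as a function of sample size."""
    sample = as_sample(data)
    n = sample.n_adjusted
    grid = default_size_grid(n) if m_grid is None else [int(m) for m in m_grid]
    return [
        CompletenessPoint(m=int(m), coverage=coverage_at_m(sample, int(m)), segment=_segment(int(m), n))
        for m in grid
    ]
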