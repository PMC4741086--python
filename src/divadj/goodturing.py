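"""Good-Turing frequency formulas and the spurious-singleton correction.

High-throughput sequencing can misclassify a read as a novel taxon, so the
observed singleton count ``f_1`` is often inflated by *spurious singletons*.
Because nearly every nonparametric diversity estimator leans on ``f_1``,
this inflation propagates into severely biased richness and diversity
estimates.

The correction implemented here estimates the *true* singleton count from
the next three frequency counts alone.  A Cauchy-Schwarz inequality on the
multinomial expectations of ``f_1, f_2, f_3`` yields a lower bound

    f1_tilde = 2 (n - 2) f_2^2 / [3 (n - 1) f_3],

and evaluating the bound's bias with the modified Good-Turing estimates of
the mean relative abundance of doubletons and tripletons gives the
bias-corrected estimator (large-n form)

    f1_hat = 2 f_2^2 / (3 f_3) + 2 f_2 [ f_2 / (3 f_3) - f_3 / (4 f_4) ].

``f1_hat`` relies only on ``f_2, f_3, f_4`` and is therefore immune to the
error-inflated singleton slot, provided those three counts are reliable.
A large ratio ``f_1 / f1_hat`` is itself diagnostic of sequencing error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .exceptions import InsufficientDataError, UndefinedEstimateError
from .freq_data import FrequencyCounts

logger = logging.getLogger(__name__)

__all__ = [
    "RareAbundanceEstimate",
    "SingletonEstimate",
    "gt_alpha",
    "gt_alpha_modified",
    "rare_abundance",
    "singleton_lower_bound",
    "estimate_singletons",
    "estimate_shifted",
    "spuriousness_diagnostic",
]


@dataclass(frozen=True)
class RareAbundanceEstimate:
    """Estimated true mean relative abundance of taxa seen ``r`` times.

    ``alpha_tilde`` is the classic Good-Turing estimate ``(r+1) f_{r+1} /
    (n f_r)``; ``alpha_hat`` is the modified estimate, which is always a
    proper probability in [0, 1].
    """

    r: int
    alpha_tilde: float
    alpha_hat: float


@dataclass(frozen=True)
class SingletonEstimate:
    """Result of the singleton-count correction.

    ``f1_tilde`` is the Cauchy-Schwarz lower bound; ``f1_hat`` the
    bias-corrected estimate (clamped at zero).  ``fallback_applied`` marks
    the sparse-tail smoothing ``f_3 -> f_3 + 1`` / ``f_4 -> f_4 + 1``;
    ``clamped`` marks a negative raw value forced to zero.
    """

    f1_tilde: float
    f1_hat: float
    fallback_applied: bool
    clamped: bool


def gt_alpha(fc: FrequencyCounts, r: int) -> float:
    """Classic Good-Turing mean relative abundance of taxa seen ``r`` times.

    Returns ``(r+1) f_{r+1} / (n f_r)`` for ``r >= 1``.  For ``r = 0`` the
    denominator class size ``f_0`` is unobservable, so the total probability
    mass ``(r+1) f_{r+1} / n = f_1 / n`` of unseen taxa is returned instead.
    """
    n = fc.n
    if n < 1:
        raise InsufficientDataError("empty sample")
    if r == 0:
        return fc.f(1) / n
    fr = fc.f(r)
    if fr == 0:
        raise UndefinedEstimateError(f"f_{r} = 0: Good-Turing estimate undefined")
    return (r + 1) * fc.f(r + 1) / (n * fr)


def gt_alpha_modified(fc: FrequencyCounts, r: int) -> float:
    """Modified Good-Turing estimate, always in [0, 1].

    ``alpha_hat_r = (r+1) f_{r+1} / [(n - r) f_r + (r+1) f_{r+1}]``.
    """
    n = fc.n
    num = (r + 1) * fc.f(r + 1)
    den = (n - r) * fc.f(r) + num
    if den <= 0:
        if num == 0:  # boundary r = n: no mass beyond the sample
            return 0.0
        raise UndefinedEstimateError(f"zero denominator in modified Good-Turing at r={r}")
    return num / den


def rare_abundance(fc: FrequencyCounts, r: int) -> RareAbundanceEstimate:
    """Bundle the classic and modified Good-Turing estimates at ``r``."""
    return RareAbundanceEstimate(
        r=r, alpha_tilde=gt_alpha(fc, r), alpha_hat=gt_alpha_modified(fc, r)
    )


def singleton_lower_bound(fc: FrequencyCounts) -> float:
    """Cauchy-Schwarz lower bound for the true singleton count.

    ``f1_tilde = 2 (n-2) f_2^2 / [3 (n-1) f_3]``; returns 0 when there are
    no doubletons.  With ``f_3 = 0`` (and ``f_2 > 0``) the bound is formally
    infinite; the sparse-tail smoothing ``f_3 -> 1`` is applied, mirroring
    :func:`estimate_singletons`.
    """
    n = fc.n
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for the singleton bound, got n={n}")
    f2 = fc.f(2)
    if f2 == 0:
        return 0.0
    f3 = fc.f(3) or 1
    return 2 * (n - 2) * f2 * f2 / (3 * (n - 1) * f3)


def estimate_singletons(fc: FrequencyCounts) -> SingletonEstimate:
    """Estimate the true singleton count from ``(f_2, f_3, f_4)``.

    ``f1_hat = 2 f_2^2/(3 f_3) + 2 f_2 (f_2/(3 f_3) - f_3/(4 f_4))``, with
    ``f_3``/``f_4`` smoothed to 1 when zero (bias-corrected-Chao1-style) and
    a negative value clamped to 0.  The estimate may legitimately exceed the
    observed ``f_1`` on error-free data; interpreting the comparison is the
    diagnostic's job, not the estimator's.
    """
    n = fc.n
    if 0 < n < 100:
        logger.warning("singleton estimator derived for large n; n=%d is small", n)
    f2, f3, f4 = fc.f(2), fc.f(3), fc.f(4)
    if f2 == 0:
        return SingletonEstimate(0.0, 0.0, fallback_applied=False, clamped=False)
    fallback = (f3 == 0) or (f4 == 0)
    if fallback:
        logger.warning("sparse tail (f3=%d, f4=%d): applying +1 smoothing", f3, f4)
    f3e, f4e = f3 or 1, f4 or 1
    tilde = singleton_lower_bound(fc) if n >= 3 else 0.0
    raw = 2 * f2 * f2 / (3 * f3e) + 2 * f2 * (f2 / (3 * f3e) - f3e / (4 * f4e))
    clamped = raw < 0
    if clamped:
        logger.warning("negative singleton estimate %.3f clamped to 0", raw)
    return SingletonEstimate(
        f1_tilde=tilde,
        f1_hat=max(raw, 0.0),
        fallback_applied=fallback,
        clamped=clamped,
    )


def estimate_shifted(fc: FrequencyCounts, r: int) -> float:
    """Estimate the true count of taxa seen ``r`` times from the next three counts.

    The singleton derivation shifts verbatim: the Cauchy-Schwarz bound on
    the expectations of ``f_r, f_{r+1}, f_{r+2}`` gives the leading term
    ``[(r+1)/(r+2)] f_{r+1}^2 / f_{r+2}`` (the large-n limit of the binomial
    coefficient ratio ``C(n,r) C(n,r+2) / C(n,r+1)^2``), and the modified
    Good-Turing ratios at ``r+1`` and ``r+2`` supply the bias correction

        (r+1) f_{r+1} [ f_{r+1} / ((r+2) f_{r+2}) - f_{r+2} / ((r+3) f_{r+3}) ].

    At ``r = 1`` this reduces exactly to :func:`estimate_singletons`.
    Zero denominators fall back to ``+1`` smoothing, and negative values
    clamp to zero, as in the singleton case.
    """
    if r < 1:
        raise InsufficientDataError(f"shift index must be >= 1, got r={r}")
    f1, f2, f3 = fc.f(r + 1), fc.f(r + 2), fc.f(r + 3)
    if f1 == 0:
        return 0.0
    f2e, f3e = f2 or 1, f3 or 1
    # arithmetic ordered to match estimate_singletons bit-for-bit at r = 1
    lead = (r + 1) * f1 * f1 / ((r + 2) * f2e)
    corr = (r + 1) * f1 * (f1 / ((r + 2) * f2e) - f2e / ((r + 3) * f3e))
    return max(lead + corr, 0.0)


def spuriousness_diagnostic(fc: FrequencyCounts, ratio_threshold: float = 2.0) -> dict:
    """Compare observed and estimated singleton counts to flag sequencing error.

    A ratio ``f_1 / f1_hat`` well above one indicates that spurious
    singletons are present.  Returns a JSON-serializable report.
    """
    est = estimate_singletons(fc)
    f1_obs = fc.f(1)
    rounded = int(math.floor(est.f1_hat + 0.5))
    ratio = f1_obs / est.f1_hat if est.f1_hat > 0 else math.inf if f1_obs else 1.0
    return {
        "f1_observed": f1_obs,
        "f1_hat_raw": est.f1_hat,
        "f1_hat": rounded,
        "ratio": ratio,
        "errors_suspected": bool(ratio > ratio_threshold),
        "fallback_applied": est.fallback_applied,
        "clamped": est.clamped,
    }
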