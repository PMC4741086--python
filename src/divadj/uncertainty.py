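"""Bootstrap SEs and confidence intervals for every estimator.

Resampling is from an *estimated bootstrap community* reconstructed from
the sample: each detected taxon with count ``X`` is assigned probability
``(X/n) [1 - lambda (1 - X/n)^n]``, with ``lambda`` tuned so that the
detected probabilities sum to the estimated sample coverage ``C_hat``; the
remaining probability ``1 - C_hat`` is split equally among ``f0_hat``
undetected taxa, where ``f0_hat`` is the Chao1 undetected-richness term
rounded up.  ``B`` multinomial resamples of size ``n`` are drawn from this
community and the statistic recomputed on each replicate; the SE is the
replicate standard deviation.

When an adjusted sample is supplied, resampling operates on the adjusted
counts (confidence bands are conditional on the singleton adjustment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .exceptions import ValidationError
from .freq_data import AdjustedSample, FrequencyCounts, as_sample, from_abundances
from .coverage_rarefy import coverage_at_n

__all__ = ["BootstrapCommunity", "build_bootstrap_community", "bootstrap_ci", "BootstrapResult"]


@dataclass(frozen=True)
class BootstrapCommunity:
    """Estimated community to resample from."""

    detected_probs: np.ndarray
    f0_hat: int
    undetected_prob_each: float
    n: int

    @property
    def probabilities(self) -> np.ndarray:
        """Full probability vector (detected first, then undetected)."""
        return np.concatenate(
            [self.detected_probs, np.full(self.f0_hat, self.undetected_prob_each)]
        )


class BootstrapResult(NamedTuple):
    se: float
    ci_lower: float
    ci_upper: float
    estimate: float
    replicates: np.ndarray


def build_bootstrap_community(data: FrequencyCounts | AdjustedSample) -> BootstrapCommunity:
    """Reconstruct the bootstrap community from a sample.

    ``lambda`` enters the detected-mass constraint linearly, so it has the
    closed-form solution ``lambda = (1 - C_hat) / sum_i (X_i/n)(1 - X_i/n)^n``.
    """
    sample = as_sample(data)
    fc, n = sample.adjusted, sample.n_adjusted
    x = fc.expand().astype(float)
    phat = x / n
    chat = coverage_at_n(sample)
    f1, f2 = fc.f(1), fc.f(2)
    a = (n - 1) / n
    f0_raw = a * f1 * f1 / (2 * f2) if f2 > 0 else a * f1 * (f1 - 1) / 2
    f0_hat = int(math.ceil(f0_raw)) if f0_raw > 0 else 0
    if f0_hat == 0 or chat >= 1.0:
        return BootstrapCommunity(
            detected_probs=phat / phat.sum(), f0_hat=0, undetected_prob_each=0.0, n=n
        )
    w = phat * (1.0 - phat) ** n
    lam = (1.0 - chat) / float(w.sum())
    detected = phat * (1.0 - lam * (1.0 - phat) ** n)
    return BootstrapCommunity(
        detected_probs=detected,
        f0_hat=f0_hat,
        undetected_prob_each=(1.0 - chat) / f0_hat,
        n=n,
    )


def bootstrap_ci(
    data: FrequencyCounts | AdjustedSample,
    statistic: Callable[[FrequencyCounts], float],
    B: int = 200,
    seed: int = 1,
    ci: str = "normal",
    level_z: float = 1.96,
) -> BootstrapResult:
    """Bootstrap SE and 95% CI for any statistic of a sample.

    ``statistic`` receives each replicate's :class:`FrequencyCounts`.
    ``ci``: ``normal`` (estimate +/- z*SE), ``lognormal`` (on the excess
    over the observed richness; appropriate for q = 0 richness), or
    ``percentile``.  A fixed seed makes the output bit-reproducible.
    """
    if B < 2:
        raise ValidationError(f"need at least 2 bootstrap replicates, got B={B}")
    sample = as_sample(data)
    community = build_bootstrap_community(sample)
    probs = community.probabilities
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        counts = rng.multinomial(community.n, probs)
        fc_b = from_abundances(counts[counts > 0])
        stats[b] = statistic(fc_b)
    est = float(statistic(sample.adjusted))
    se = float(np.std(stats, ddof=1))
    if ci == "percentile":
        lo, hi = (float(v) for v in np.quantile(stats, [0.025, 0.975]))
    elif ci == "lognormal":
        s_obs = sample.adjusted.s_obs
        d = est - s_obs
        if d <= 0 or se == 0:
            lo, hi = float(s_obs), est
        else:
            big_r = math.exp(level_z * math.sqrt(math.log(1 + se * se / (d * d))))
            lo, hi = s_obs + d / big_r, s_obs + d * big_r
    elif ci == "normal":
        lo, hi = est - level_z * se, est + level_z * se
    else:
        raise ValidationError(f"unknown ci style {ci!r}")
    return BootstrapResult(se=se, ci_lower=float(lo), ci_upper=float(hi), estimate=est, replicates=stats)
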