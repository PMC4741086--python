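"""Chao1 and adjusted-Chao1 species richness with analytic SE and CIs.

Chao1 is the classic nonparametric lower bound for species richness,
``S_obs + [(n-1)/n] f_1^2 / (2 f_2)``.  When the singleton count is
inflated by sequencing error the bound explodes; the *adjusted* Chao1
replaces ``f_1`` by the estimated true singleton count (and uses the
adjusted sample size throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import InsufficientDataError
from .freq_data import AdjustedSample, FrequencyCounts, as_sample

__all__ = ["RichnessEstimate", "chao1", "chao1_adjusted", "chao1_variance_ci"]


@dataclass(frozen=True)
class RichnessEstimate:
    """A richness point estimate with optional SE and 95% CI.

    ``variant`` records which formula produced it: ``classic`` /
    ``classic_bc`` (bias-corrected ``f_2 = 0`` branch) on raw counts,
    ``adjusted`` / ``adjusted_bc`` on singleton-adjusted samples.
    """

    estimate: float
    s_obs: int
    variant: str
    se: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "estimate": self.estimate,
            "s_obs": self.s_obs,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }


def chao1(fc: FrequencyCounts, small_sample_correction: bool = True) -> RichnessEstimate:
    """Classic Chao1 richness lower bound on raw frequency counts.

    ``small_sample_correction`` toggles the ``(n-1)/n`` factor; some
    published tables omit it (the difference is negligible for large n).
    With ``f_2 = 0`` the bias-corrected branch
    ``S_obs + [(n-1)/n] f_1 (f_1 - 1) / 2`` is used.
    """
    n = fc.n
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for Chao1, got n={n}")
    f1, f2 = fc.f(1), fc.f(2)
    a = (n - 1) / n if small_sample_correction else 1.0
    if f2 > 0:
        est = fc.s_obs + a * f1 * f1 / (2 * f2)
        variant = "classic"
    else:
        est = fc.s_obs + a * f1 * (f1 - 1) / 2
        variant = "classic_bc"
    return RichnessEstimate(estimate=est, s_obs=fc.s_obs, variant=variant)


def chao1_adjusted(sample: AdjustedSample | FrequencyCounts) -> RichnessEstimate:
    """Chao1 on the singleton-adjusted data.

    With the adjusted sample size ``n`` and estimated singletons ``f1_hat``:
    ``S_obs_adj + [(n-1)/n] f1_hat^2 / (2 f_2)`` when ``f_2 > 0``, else the
    bias-corrected ``S_obs_adj + f1_hat (f1_hat - 1) / [2 (f_2 + 1)]``.
    """
    sample = as_sample(sample)
    fc = sample.adjusted
    n = sample.n_adjusted
    f1, f2 = sample.f1_hat, fc.f(2)
    if f2 > 0:
        est = fc.s_obs + (n - 1) / n * f1 * f1 / (2 * f2)
        variant = "adjusted"
    else:
        est = fc.s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        variant = "adjusted_bc"
    return RichnessEstimate(estimate=est, s_obs=fc.s_obs, variant=variant)


def _chao1_variance(n: int, f1: float, f2: float, estimate: float, s_obs: int) -> float:
    """Analytic variance of the Chao1 form with the singleton slot's value.

    ``f_2 > 0`` branch (ratio ``r = f1/f2``, ``A = (n-1)/n``):
    ``var = f2 [A^2 r^4 / 4 + A^2 r^3 + A r^2 / 2]``.  The ``f_2 = 0``
    branch uses the standard bias-corrected form.
    """
    a = (n - 1) / n
    if f2 > 0:
        r = f1 / f2
        return f2 * (a * a * r**4 / 4 + a * a * r**3 + a * r * r / 2)
    if f1 == 0:
        return 0.0
    var = (
        a * f1 * (f1 - 1) / 2
        + a * a * f1 * (2 * f1 - 1) ** 2 / 4
    )
    if estimate > 0:
        var -= a * a * f1**4 / (4 * estimate)
    return max(var, 0.0)


def chao1_variance_ci(
    est: RichnessEstimate,
    sample: AdjustedSample | FrequencyCounts,
    level_z: float = 1.96,
) -> RichnessEstimate:
    """Attach the analytic SE and 95% log-normal CI to a richness estimate.

    The CI is on the undetected part ``est - S_obs``:
    ``lower = S_obs + (est - S_obs)/R`` and ``upper = S_obs + (est - S_obs) R``
    with ``R = exp{z sqrt(log(1 + var/(est - S_obs)^2))}``, so the lower
    limit can never drop below the observed richness.
    """
    sample = as_sample(sample)
    fc = sample.adjusted
    n = sample.n_adjusted
    var = _chao1_variance(n, sample.f1_hat, fc.f(2), est.estimate, est.s_obs)
    se = math.sqrt(var)
    d = est.estimate - est.s_obs
    if d <= 0 or var == 0:
        return replace(est, se=se, ci_lower=float(est.s_obs), ci_upper=float(est.estimate))
    big_r = math.exp(level_z * math.sqrt(math.log(1 + var / (d * d))))
    return replace(
        est, se=se, ci_lower=est.s_obs + d / big_r, ci_upper=est.s_obs + d * big_r
    )
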