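"""Synthetic communities, multinomial sampling, and sequencing-error injection.

The generator emulates the study conditions under which the singleton
correction was characterized: a community of ``S = 2,000`` taxa with a
configurable species-abundance distribution, multinomial samples of
``n = 2,000 .. 10,000`` reads, and a per-read misclassification probability
``epsilon`` (default scenarios use 0.1).  An error event relabels the read
as a brand-new taxon, so every error contributes exactly one *spurious
singleton* — errors are modeled at the classification level, not at the
base-call level.

Community heterogeneity is summarized by the CV of the relative abundances
(SD/mean; 0 for a perfectly even community).  Several parametric
abundance families spanning a wide CV range are provided.
"""

from __future__ import annotations
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .freq_data import FrequencyCounts, from_abundances
from .goodturing import estimate_singletons

__all__ = [
    "CommunityModel",
    "ErrorModel",
    "TruthRecord",
    "make_model",
    "draw_sample",
    "evaluate_singleton_estimator",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("uniform", "geometric", "lognormal", "zipf_mandelbrot", "broken_stick", "custom")


@dataclass(frozen=True)
class CommunityModel:
    """Ground-truth community: taxa count, relative abundances, heterogeneity."""

    S: int
    p: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.size != self.S or self.S < 2:
            raise ValidationError(f"need S >= 2 abundances, got S={self.S}, len(p)={p.size}")
        if np.any(p <= 0):
            raise ValidationError("all relative abundances must be > 0")
        object.__setattr__(self, "p", p / p.sum())

    @property
    def cv(self) -> float:
        """SD/mean of the relative abundances (population SD)."""
        return float(np.std(self.p) / np.mean(self.p))


@dataclass(frozen=True)
class ErrorModel:
    """Per-read misclassification: each error spawns a unique spurious singleton."""

    epsilon: float = 0.0
    mode: str = "unique_spurious"

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValidationError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if self.mode != "unique_spurious":
            raise ValidationError(f"unknown error mode {self.mode!r}")


class TruthRecord(NamedTuple):
    """What actually happened in one simulated sample."""

    error_free: FrequencyCounts
    n_spurious: int
    f1_true: int


def make_model(family: str, S: int = 2000, **params) -> CommunityModel:
    """Construct a community abundance model.

    Families and their parameters:

    - ``uniform``: perfectly even, CV = 0.
    - ``geometric(ratio=0.99)``: ``p_i ~ ratio^i``, 0 < ratio < 1.
    - ``lognormal(sigma=1.0)``: abundances proportional to the quantiles of
      a lognormal (deterministic, no sampling noise in the model itself).
    - ``zipf_mandelbrot(a=1.0, b=5.0)``: ``p_i ~ (i + b)^(-a)``.
    - ``broken_stick``: MacArthur's expected broken-stick abundances.
    - ``custom(p=...)``: explicit abundance vector.
    """
    if family not in MODEL_FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {MODEL_FAMILIES}")
    if S < 2:
        raise ValidationError(f"need S >= 2, got S={S}")
    i = np.arange(1, S + 1, dtype=float)
    if family == "uniform":
        p = np.full(S, 1.0 / S)
    elif family == "geometric":
        ratio = float(params.pop("ratio", 0.99))
        if not (0.0 < ratio < 1.0):
            raise ValidationError(f"geometric ratio must be in (0, 1), got {ratio}")
        p = ratio**i
    elif family == "lognormal":
        sigma = float(params.pop("sigma", 1.0))
        if sigma < 0:
            raise ValidationError(f"lognormal sigma must be >= 0, got {sigma}")
        quantiles = (i - 0.5) / S
        from scipy.stats import norm

        p = np.exp(sigma * norm.ppf(quantiles))
    elif family == "zipf_mandelbrot":
        a = float(params.pop("a", 1.0))
        b = float(params.pop("b", 5.0))
        if a <= 0 or b < 0:
            raise ValidationError(f"need a > 0 and b >= 0, got a={a}, b={b}")
        p = (i + b) ** (-a)
    elif family == "broken_stick":
        p = np.array([np.sum(1.0 / np.arange(j, S + 1)) for j in range(1, S + 1)]) / S
    else:  # custom
        p = np.asarray(params.pop("p"), dtype=float)
        S = p.size
    if params:
        raise ValidationError(f"unused parameters for family {family!r}: {sorted(params)}")
    return CommunityModel(S=S, p=p, label=family)


def draw_sample(
    model: CommunityModel,
    n: int,
    error: ErrorModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[FrequencyCounts, TruthRecord]:
    """Draw one multinomial sample of size ``n``, optionally error-injected.

    Each of the ``n`` reads is first assigned a true taxon; with probability
    ``epsilon`` it is then misclassified to a never-before-seen taxon and
    becomes a spurious singleton.  Returns the observed counts and a truth
    record holding the error-free counts and the number of spurious reads.
    Multinomial and error draws consume one seeded stream in a fixed order.
    """
    if n < 1:
        raise ValidationError(f"need n >= 1, got n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts_true = rng.multinomial(n, model.p)
    error_free = from_abundances(counts_true[counts_true > 0])
    eps = error.epsilon if error is not None else 0.0
    if eps > 0.0:
        spurious_per_taxon = rng.binomial(counts_true, eps)
        n_spurious = int(spurious_per_taxon.sum())
        surviving = counts_true - spurious_per_taxon
        observed_counts = {}
        for k, f in from_abundances(surviving[surviving > 0]).counts.items():
            observed_counts[k] = f
        observed_counts[1] = observed_counts.get(1, 0) + n_spurious
        observed = FrequencyCounts(observed_counts)
    else:
        n_spurious = 0
        observed = error_free
    return observed, TruthRecord(
        error_free=error_free, n_spurious=n_spurious, f1_true=error_free.f(1)
    )


def evaluate_singleton_estimator(
    models: Sequence[CommunityModel] | CommunityModel,
    n_grid: Iterable[int] | None = None,
    epsilon: float = 0.1,
    reps: int = 100,
    seed: int = 1,
) -> pd.DataFrame:
    """Simulation harness: singleton estimator vs. truth across models and sizes.

    For each (model, n) cell, ``reps`` paired samples are drawn with and
    without error injection; the singleton estimator is applied to the
    error-injected data.  Columns: model, cv, n, mean true ``f_1``
    (error-free data), mean observed ``f_1`` (error-injected data), mean
    ``f1_hat``, and the RMSE of ``f1_hat`` against the error-free ``f_1``.
    """
    if reps < 2:
        raise ValidationError(f"need reps >= 2, got {reps}")
    if isinstance(models, CommunityModel):
        models = [models]
    n_values = list(n_grid) if n_grid is not None else list(range(2000, 10001, 2000))
    error = ErrorModel(epsilon=epsilon)
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        for n in n_values:
            f1_true = np.empty(reps)
            f1_obs = np.empty(reps)
            f1_hat = np.empty(reps)
            for r in range(reps):
                observed, truth = draw_sample(model, n, error=error, seed=rng)
                f1_true[r] = truth.f1_true
                f1_obs[r] = observed.f(1)
                f1_hat[r] = estimate_singletons(observed).f1_hat
            rows.append(
                {
                    "model": model.label,
                    "cv": model.cv,
                    "n": n,
                    "f1_true_mean": f1_true.mean(),
                    "f1_observed_mean": f1_obs.mean(),
                    "f1_hat_mean": f1_hat.mean(),
                    "rmse": float(np.sqrt(np.mean((f1_hat - f1_true) ** 2))),
                }
            )
    return pd.DataFrame(rows)
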