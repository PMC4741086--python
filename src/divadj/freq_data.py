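"""Abundance frequency counts: the package's universal data model, with I/O.

A sample from a community is summarized by its *abundance frequency counts*
``f_k``: the number of taxa observed exactly ``k`` times among the ``n``
sequenced individuals.  Singletons (``f_1``) are taxa seen once, doubletons
(``f_2``) twice, and so on.  Every estimator in this package consumes either
a :class:`FrequencyCounts` or an :class:`AdjustedSample` — a sample whose
observed singleton count has been replaced by a nonparametric estimate of
the *true* singleton count (sequencing errors inflate ``f_1`` by spawning
spurious novel taxa).

Counts are stored sparsely (a map ``k -> f_k``); the multiplicity ``k`` can
range up to ``n``, so a dense array is never materialized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "FrequencyCounts",
    "AdjustedSample",
    "from_abundances",
    "build_adjusted",
    "read_counts",
    "write_counts",
    "read_abundances",
    "load_virome",
    "FIXTURES",
]

#: Names of the packaged virome fixtures (pooled contig-spectrum counts).
FIXTURES = ("swine_feces", "reclaimed_water")


@dataclass(frozen=True)
class FrequencyCounts:
    """Sparse frequency counts ``k -> f_k`` with derived totals.

    Attributes
    ----------
    counts : dict[int, int]
        Mapping from multiplicity ``k >= 1`` to the number of taxa observed
        exactly ``k`` times.  Zero-valued entries are dropped on
        construction.
    """

    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, f in self.counts.items():
            ki, fi = int(k), int(f)
            if ki != k or fi != f:
                raise ValidationError(f"non-integer entry k={k!r}, f={f!r}")
            if ki < 1:
                raise ValidationError(f"multiplicity must be >= 1, got {ki}")
            if fi < 0:
                raise ValidationError(f"negative count f_{ki} = {fi}")
            if fi > 0:
                clean[ki] = fi
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    # -- derived totals -------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of individuals, ``sum(k * f_k)``."""
        return int(sum(k * f for k, f in self.counts.items()))

    @property
    def s_obs(self) -> int:
        """Number of observed taxa, ``sum(f_k)``."""
        return int(sum(self.counts.values()))

    # -- accessors ------------------------------------------------------
    def f(self, k: int) -> int:
        """Return ``f_k`` (0 if absent)."""
        return self.counts.get(int(k), 0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return parallel arrays ``(ks, fs)`` sorted by multiplicity."""
        ks = np.fromiter(self.counts.keys(), dtype=np.int64)
        fs = np.fromiter(self.counts.values(), dtype=np.int64)
        return ks, fs

    def expand(self) -> np.ndarray:
        """Expand to a per-taxon abundance vector (``k`` repeated ``f_k`` times)."""
        ks, fs = self.arrays()
        return np.repeat(ks, fs)

    def replace_singletons(self, f1: int) -> "FrequencyCounts":
        """Return a copy with the ``k = 1`` slot set to ``f1``."""
        if f1 < 0:
            raise ValidationError(f"singleton count must be >= 0, got {f1}")
        counts = {k: f for k, f in self.counts.items() if k != 1}
        if f1 > 0:
            counts[1] = int(f1)
        return FrequencyCounts(counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyCounts):
            return NotImplemented
        return self.counts == other.counts


@dataclass(frozen=True)
class AdjustedSample:
    """A sample whose singleton slot holds the estimated true count.

    Attributes
    ----------
    adjusted : FrequencyCounts
        The original counts with ``f_1`` replaced by ``f1_hat``.
    f1_observed : int
        The (possibly spurious) observed singleton count.
    f1_hat_raw : float
        The unrounded singleton estimate.
    f1_hat : int
        ``f1_hat_raw`` rounded half-up to the nearest integer (tables print
        integer counts; the raw value is retained for reporting).
    n_adjusted : int
        Sample size of the adjusted data, ``n - f1_observed + f1_hat``.
    """

    adjusted: FrequencyCounts
    f1_observed: int
    f1_hat_raw: float
    f1_hat: int
    n_adjusted: int

    @property
    def s_obs(self) -> int:
        return self.adjusted.s_obs

    def as_dict(self) -> dict:
        return {
            "f1_observed": self.f1_observed,
            "f1_hat_raw": self.f1_hat_raw,
            "f1_hat": self.f1_hat,
            "n_adjusted": self.n_adjusted,
            "s_obs_adjusted": self.s_obs,
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def from_abundances(abundances: Iterable[int]) -> FrequencyCounts:
    """Tabulate a per-taxon abundance vector into frequency counts.

    Raises :class:`ValidationError` naming the offending index if any
    abundance is non-positive or non-integer.
    """
    arr = np.asarray(abundances if isinstance(abundances, np.ndarray) else list(abundances))
    if arr.size == 0:
        return FrequencyCounts({})
    if not np.issubdtype(arr.dtype, np.number):
        bad = next(i for i, x in enumerate(arr) if not isinstance(x, (int, np.integer)))
        raise ValidationError(
            f"abundance at index {bad} must be a positive integer, got {arr[bad]!r}"
        )
    as_int = arr.astype(np.int64)
    invalid = (as_int != arr) | (as_int < 1)
    if np.any(invalid):
        bad = int(np.argmax(invalid))
        raise ValidationError(
            f"abundance at index {bad} must be a positive integer, got {arr[bad]!r}"
        )
    ks, fs = np.unique(as_int, return_counts=True)
    return FrequencyCounts({int(k): int(f) for k, f in zip(ks, fs)})


def build_adjusted(fc: FrequencyCounts, f1_hat_raw: float) -> AdjustedSample:
    """Replace the observed singleton count by an estimated one.

    Only the ``k = 1`` slot changes; all other counts are carried over, and
    the adjusted sample size is ``n - f1_observed + round(f1_hat_raw)``.
    """
    if f1_hat_raw < 0:
        raise ValidationError(f"estimated singleton count must be >= 0, got {f1_hat_raw}")
    f1_obs = fc.f(1)
    f1_hat = _round_half_up(float(f1_hat_raw))
    adjusted = fc.replace_singletons(f1_hat)
    return AdjustedSample(
        adjusted=adjusted,
        f1_observed=f1_obs,
        f1_hat_raw=float(f1_hat_raw),
        f1_hat=f1_hat,
        n_adjusted=fc.n - f1_obs + f1_hat,
    )


def as_sample(data: FrequencyCounts | AdjustedSample) -> AdjustedSample:
    """Coerce plain counts to an :class:`AdjustedSample` (identity adjustment).

    Estimators written against adjusted samples can then run unchanged on
    original data: the singleton slot simply keeps its observed value.
    """
    if isinstance(data, AdjustedSample):
        return data
    return build_adjusted(data, float(data.f(1)))


# ----------------------------------------------------------------------
# I/O: two-column delimited text for counts, one/two-column for abundances
# ----------------------------------------------------------------------

def _sniff_delimiter(line: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if ("," in line and "\t" not in line) else None  # type: ignore[return-value]


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_counts(path: str | Path, dialect: str | None = None) -> FrequencyCounts:
    """Read frequency counts from two-column delimited text ``(k, f_k)``.

    Comment lines (``#``) are skipped; a single non-numeric header row is
    tolerated; duplicate ``k`` rows and malformed rows raise
    :class:`ValidationError` with the line number.
    """
    counts: dict[int, int] = {}
    first = True
    for lineno, line in _data_lines(path):
        delim = _sniff_delimiter(line, dialect)
        fields = [s for s in (line.split(delim) if delim else line.split()) if s != ""]
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            k, f = int(fields[0]), int(fields[1])
        except ValueError:
            if first:  # header row
                first = False
                continue
            raise ValidationError(f"{path}:{lineno}: non-integer row {fields!r}") from None
        first = False
        if k in counts:
            raise ValidationError(f"{path}:{lineno}: duplicate multiplicity k={k}")
        if f < 0:
            raise ValidationError(f"{path}:{lineno}: negative count f_{k}={f}")
        counts[k] = f
    return FrequencyCounts(counts)


def write_counts(fc: FrequencyCounts, path: str | Path, dialect: str = "tsv") -> None:
    """Write counts sorted by ``k`` as tab- (or comma-) delimited text."""
    delim = "," if dialect == "csv" else "\t"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["k", "f_k"])
        for k, f in fc.counts.items():
            writer.writerow([k, f])


def read_abundances(path: str | Path, dialect: str | None = None) -> FrequencyCounts:
    """Read a per-taxon abundance vector and tabulate it.

    Accepts one integer per line, or ``taxon<delim>count`` rows
    (auto-detected by column count).
    """
    values: list[int] = []
    for lineno, line in _data_lines(path):
        delim = _sniff_delimiter(line, dialect)
        fields = [s for s in (line.split(delim) if delim else line.split()) if s != ""]
        raw = fields[-1] if len(fields) == 2 else fields[0]
        if len(fields) > 2:
            raise ValidationError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(fields)}")
        try:
            values.append(int(raw))
        except ValueError:
            if lineno == 1:
                continue  # header
            raise ValidationError(f"{path}:{lineno}: non-integer abundance {raw!r}") from None
    return from_abundances(values)


def load_virome(name: str) -> FrequencyCounts:
    """Load a packaged virome contig-spectrum fixture.

    ``name`` is one of ``"swine_feces"`` (pooled contig spectra of seven
    non-medicated swine fecal viromes) or ``"reclaimed_water"`` (four pooled
    reclaimed fresh-water viromes).
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    ref = resources.files("divadj").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        return read_counts(path, dialect="tsv")
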