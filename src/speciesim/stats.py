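"""Output statistics: mean similarity, cumulative speciation curves,
abundance distributions, richness summaries, and two-sample comparison."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .species import SpeciationEvent

__all__ = [
    "NoSpeciationError",
    "mean_similarity",
    "cumulative_speciation_curve",
    "AbundanceDistribution",
    "incipient_abundance_distribution",
    "final_abundance_distribution",
    "singleton_fraction",
    "ks_two_sample",
    "richness_summary",
]


class NoSpeciationError(ValueError):
    """Raised when a distribution is requested but no events occurred."""


def mean_similarity(q: np.ndarray) -> float:
    """Mean over the N(N-1)/2 off-diagonal pairs of a similarity matrix."""
    q = np.asarray(q)
    n = q.shape[0]
    if q.ndim != 2 or q.shape[1] != n:
        raise ValueError(f"expected a square matrix, got shape {q.shape}")
    if n < 2:
        raise ValueError("mean similarity needs at least two individuals")
    return float((q.sum() - np.trace(q)) / (n * (n - 1)))


def cumulative_speciation_curve(
    events: Sequence[SpeciationEvent], horizon: int
) -> np.ndarray:
    """Nondecreasing step series: cumulative event count at generations
    0..horizon (events beyond the horizon are ignored)."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    gens = np.array([e.generation for e in events], dtype=int)
    if gens.size and gens.min() < 0:
        raise ValueError("event generations must be >= 0")
    counts = np.zeros(horizon + 1, dtype=int)
    inside = gens[gens <= horizon]
    np.add.at(counts, inside, 1)
    return np.cumsum(counts)


@dataclass(frozen=True)
class AbundanceDistribution:
    """Sorted abundance sample with its normalised histogram."""

    abundances: np.ndarray          # sorted ascending, positive ints
    histogram: dict[int, float]     # abundance -> relative frequency

    @property
    def n_samples(self) -> int:
        return int(self.abundances.size)

    def mean(self) -> float:
        return float(self.abundances.mean())


def _make_distribution(values: Iterable[int]) -> AbundanceDistribution:
    arr = np.sort(np.asarray(list(values), dtype=int))
    if arr.size == 0 or arr.min() < 1:
        raise ValueError("abundances must be positive integers")
    total = arr.size
    hist = {int(k): v / total for k, v in sorted(Counter(arr.tolist()).items())}
    return AbundanceDistribution(abundances=arr, histogram=hist)


def incipient_abundance_distribution(
    events: Sequence[SpeciationEvent],
) -> AbundanceDistribution:
    """Distribution of new-species sizes at the moment of fission."""
    if not events:
        raise NoSpeciationError("no speciation events recorded")
    return _make_distribution(e.incipient_abundance for e in events)


def final_abundance_distribution(labeling: np.ndarray) -> AbundanceDistribution:
    """Standing species-abundance distribution of a community snapshot."""
    _, counts = np.unique(np.asarray(labeling), return_counts=True)
    return _make_distribution(counts.tolist())


def singleton_fraction(sizes: Iterable[int]) -> float:
    arr = np.asarray(list(sizes), dtype=int)
    if arr.size == 0:
        raise NoSpeciationError("empty size sample")
    return float((arr == 1).mean())


def ks_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Classical two-sample Kolmogorov-Smirnov test (maximum ECDF gap).

    Returns (statistic, p_value) with the asymptotic p-value; use
    ``method="exact"`` semantics via scipy directly if small-sample
    exactness is needed. ``alternative="greater"`` tests whether sample_a
    is stochastically smaller than sample_b (its empirical CDF lies above
    sample_b's somewhere), following the CDF-based convention of
    :func:`scipy.stats.ks_2samp`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, alternative=alternative, method="asymp")
    return float(res.statistic), float(res.pvalue)


def richness_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell richness summary of a parameter sweep.

    Expects one row per replicate with columns ``mode``, ``mu``, ``d_c``
    and ``richness`` (plus anything else, which is ignored); returns
    min/median/max richness indexed by (mode, mu, d_c).
    """
    required = {"mode", "mu", "d_c", "richness"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    out = (
        results.groupby(["mode", "mu", "d_c"])["richness"]
        .agg(["min", "median", "max", "count"])
        .rename(columns={"count": "n_replicates"})
    )
    return out
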