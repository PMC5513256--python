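"""Drawing individuals from an assemblage by inverse-CDF lookup.

Sampling is with replacement from the ranked catch-probability vector:
uniform variates on [0, 1) are matched against the cumulative distribution by
binary search, which identifies the sampled species by rank.  With-replacement
sampling matches the assumption under which the nonparametric richness
estimators are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

from .sad import Assemblage

__all__ = ["AbundanceSample", "draw_sample", "freq_of_freq", "as_rng"]


def as_rng(seed) -> np.random.Generator:
    """Normalise an int seed / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AbundanceSample:
    """Per-species counts from one abundance sample.

    ``counts`` maps a species identifier (rank for simulated data, opaque
    string for empirical data) to its positive count.
    """

    counts: Mapping[Hashable, int]

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if int(c) != c or c <= 0:
                raise ValueError(f"count for species {sp!r} must be a positive integer, got {c}")

    @property
    def n(self) -> int:
        """Sample size (number of individuals)."""
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        """Number of species observed at least once."""
        return len(self.counts)

    @property
    def freq_counts(self) -> dict[int, int]:
        """Frequency-of-frequencies map k -> f_k."""
        return freq_of_freq(self)

    def count_vector(self) -> np.ndarray:
        """Counts as an integer vector (order of insertion)."""
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))

    def f(self, k: int) -> int:
        """Number of species observed exactly k times (f_1 = singletons)."""
        return self.freq_counts.get(k, 0)


def draw_sample(assemblage: Assemblage, n: int, seed=None) -> AbundanceSample:
    """Draw ``n`` individuals with replacement from an assemblage.

    Each of ``n`` uniform variates is mapped to a species rank through the
    cumulative catch-probability vector (half-open classes
    ``[cum_{i-1}, cum_i)``) by binary search.  The same seed always yields the
    same sample.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = as_rng(seed)
    u = rng.random(n)
    ranks = np.searchsorted(assemblage.cumprobs, u, side="right")
    cnt = np.bincount(ranks, minlength=assemblage.S)
    observed = np.flatnonzero(cnt)
    return AbundanceSample({int(r) + 1: int(cnt[r]) for r in observed})


def freq_of_freq(sample: AbundanceSample) -> dict[int, int]:
    """Tabulate f_k: the number of species observed exactly k times."""
    out: dict[int, int] = {}
    for c in sample.counts.values():
        out[c] = out.get(c, 0) + 1
    return out
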