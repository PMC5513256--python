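"""Random splitting of one abundance sample into k equal incidence sub-samples.

The method: take the n counted individuals of a single sample, deal them at
random into k groups whose sizes differ by at most one, record which species
occur in each group (a species discovery matrix), and apply an incidence-based
estimator.  Because a single random partition is noisy, the partition is
redrawn many times and the per-partition estimates aggregated (mean by
default; the mean is slightly more accurate than the median).

Dealing a uniformly random permutation of individuals into fixed-size groups
is distributionally identical to sequential multivariate hypergeometric draws
of per-species group counts, which is how the partition is generated here
(no explicit permutation of n individuals is required).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import (
    ABUNDANCE_ESTIMATORS,
    INCIDENCE_ESTIMATORS,
    IncidenceSet,
    _chao2_vec,
    _ice_m2_vec,
    _jk1_vec,
    _jk2_vec,
)
from .sampling import AbundanceSample, as_rng

__all__ = ["SplitEstimate", "split_sample", "split_estimate", "SplitRichness"]


def _group_sizes(n: int, k: int) -> np.ndarray:
    """Group sizes differing by at most one; larger groups first."""
    base, rem = divmod(n, k)
    return np.array([base + 1] * rem + [base] * (k - rem), dtype=np.int64)


def _split_counts(counts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly partition a count vector into a (k, S) matrix of group counts.

    Equivalent to permuting the n individuals uniformly and dealing them into
    k near-equal groups: each group's per-species counts are a multivariate
    hypergeometric draw from what remains.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} groups")
    sizes = _group_sizes(n, k)
    out = np.empty((k, counts.size), dtype=np.int64)
    remaining = counts
    for j in range(k - 1):
        out[j] = rng.multivariate_hypergeometric(remaining, int(sizes[j]))
        remaining = remaining - out[j]
    out[k - 1] = remaining
    return out


def split_sample(sample: AbundanceSample, k: int = 2, seed=None) -> IncidenceSet:
    """One random partition of a sample into k groups, as incidence data.

    Each group contributes one presence/absence column; the returned
    incidence set records, per species, how many of the k groups contain it.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = as_rng(seed)
    species = list(sample.counts.keys())
    groups = _split_counts(sample.count_vector(), k, rng)
    present = groups > 0
    inc = present.sum(axis=0)
    return IncidenceSet(k, {sp: int(q) for sp, q in zip(species, inc) if q > 0})


@dataclass(frozen=True)
class SplitEstimate:
    """Aggregated richness estimate over repeated random splits."""

    estimator_id: str
    k: int
    n_splits: int
    per_split_estimates: np.ndarray
    aggregate: float
    split_variance: float
    aggregate_kind: str = "mean"
    fallback_count: int = 0


def _split_stats_k2(
    counts: np.ndarray, n_splits: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (s_obs, q1, q2) over ``n_splits`` independent 2-way splits."""
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    n1 = int(_group_sizes(n, 2)[0])
    # the "marginals" sampler scales with the number of species, "count" with
    # the number of individuals; pick whichever is cheaper
    method = "marginals" if n > 20 * counts.size else "count"
    g1 = rng.multivariate_hypergeometric(counts, n1, size=n_splits, method=method)
    g2 = counts[None, :] - g1
    in1 = g1 > 0
    in2 = g2 > 0
    incidence = in1.astype(np.int8) + in2.astype(np.int8)
    s_obs = (incidence > 0).sum(axis=1)
    q1 = (incidence == 1).sum(axis=1)
    q2 = (incidence == 2).sum(axis=1)
    return s_obs, q1, q2


def _estimates_from_q(estimator_id, s_obs, q1, q2):
    """Incidence estimates from vectorised m=2 split statistics."""
    if estimator_id == "chao2_bc":
        return _chao2_vec(s_obs, 2, q1, q2), 0
    if estimator_id in ("jk1i", "jk2i"):
        # identical at m = 2; the order-2 term vanishes
        if estimator_id == "jk1i":
            return _jk1_vec(s_obs, 2, q1), 0
        return _jk2_vec(s_obs, 2, q1, q2), 0
    if estimator_id == "ice":
        est, bad = _ice_m2_vec(s_obs, q1, q2)
        return est, int(bad.sum())
    raise ValueError(f"unknown incidence estimator {estimator_id!r}")


def split_estimate(
    sample: AbundanceSample,
    estimator_id: str = "chao2_bc",
    k: int = 2,
    n_splits: int = 300,
    aggregate: str = "mean",
    seed=None,
) -> SplitEstimate:
    """Estimate richness from one sample via repeated random k-way splits.

    Parameters
    ----------
    sample : AbundanceSample
        The single abundance sample to split.
    estimator_id : str
        An incidence-based estimator: chao2_bc, jk1i, jk2i or ice.
    k : int
        Number of near-equal groups per partition (2 recommended).
    n_splits : int
        Number of independent random partitions to aggregate over.
    aggregate : {"mean", "median"}
        How to combine per-split estimates; the mean is the default.
    seed : int, numpy Generator or None
        Randomness for the partitions; fixed seeds reproduce exactly.
    """
    if estimator_id in ABUNDANCE_ESTIMATORS:
        raise ValueError(
            f"{estimator_id} is abundance-based; apply it to the unsplit sample "
            "instead of the splitting path"
        )
    if estimator_id not in INCIDENCE_ESTIMATORS:
        raise ValueError(f"unknown incidence estimator {estimator_id!r}")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = as_rng(seed)
    counts = sample.count_vector()

    fallbacks = 0
    if k == 2:
        s_obs, q1, q2 = _split_stats_k2(counts, n_splits, rng)
        ests, fallbacks = _estimates_from_q(estimator_id, s_obs, q1, q2)
        ests = np.asarray(ests, dtype=float)
    else:
        species = list(sample.counts.keys())
        fn = INCIDENCE_ESTIMATORS[estimator_id]
        ests = np.empty(n_splits)
        import warnings as _warnings

        for j in range(n_splits):
            groups = _split_counts(counts, k, rng)
            inc_counts = (groups > 0).sum(axis=0)
            inc = IncidenceSet(
                k, {sp: int(q) for sp, q in zip(species, inc_counts) if q > 0}
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = fn(inc)
            ests[j] = res.estimate
            fallbacks += int(res.fallback)

    agg = float(np.mean(ests)) if aggregate == "mean" else float(np.median(ests))
    var = float(np.var(ests)) if n_splits > 1 else 0.0
    return SplitEstimate(estimator_id, k, n_splits, ests, agg, var, aggregate, fallbacks)


class SplitRichness:
    """Split-based richness estimation model for a single abundance sample.

    Statsmodels-flavoured front end to :func:`split_estimate`::

        model = SplitRichness(sample, estimator="chao2_bc", k=2)
        res = model.fit(n_splits=300, seed=1)
        print(res.summary())

    Parameters
    ----------
    sample : AbundanceSample or mapping species -> count
    estimator : str
        Incidence estimator applied to each random partition.
    k : int
        Number of groups per partition.
    """

    def __init__(self, sample, estimator: str = "chao2_bc", k: int = 2) -> None:
        if not isinstance(sample, AbundanceSample):
            sample = AbundanceSample(dict(sample))
        if estimator not in INCIDENCE_ESTIMATORS:
            raise ValueError(
                f"estimator must be incidence-based {tuple(INCIDENCE_ESTIMATORS)}, "
                f"got {estimator!r}"
            )
        self.sample = sample
        self.estimator = estimator
        self.k = int(k)

    def fit(
        self, n_splits: int = 300, aggregate: str = "mean", seed=None
    ) -> "SplitRichnessResults":
        se = split_estimate(
            self.sample, self.estimator, self.k, n_splits, aggregate, seed
        )
        return SplitRichnessResults(self, se)


class SplitRichnessResults:
    """Results of a :class:`SplitRichness` fit."""

    def __init__(self, model: SplitRichness, split: SplitEstimate) -> None:
        self.model = model
        self._split = split
        self.estimate = split.aggregate
        self.split_variance = split.split_variance
        self.per_split_estimates = split.per_split_estimates
        self.n_splits = split.n_splits
        self.fallback_count = split.fallback_count

    @property
    def split_se(self) -> float:
        """Standard deviation of the per-split estimates."""
        return float(np.sqrt(self.split_variance))

    def summary(self) -> str:
        s = self.model.sample
        lines = [
            "Split-based richness estimation",
            "=" * 47,
            f"{'estimator':<28}{self.model.estimator:>19}",
            f"{'splits (k)':<28}{self.model.k:>19d}",
            f"{'random partitions':<28}{self.n_splits:>19d}",
            f"{'sample size n':<28}{s.n:>19d}",
            f"{'observed richness s_obs':<28}{s.s_obs:>19d}",
            f"{'aggregate ({})'.format(self._split.aggregate_kind):<28}"
            f"{self.estimate:>19.4f}",
            f"{'split variance':<28}{self.split_variance:>19.4f}",
            f"{'split std. dev.':<28}{self.split_se:>19.4f}",
            f"{'estimator fallbacks':<28}{self.fallback_count:>19d}",
            "=" * 47,
        ]
        return "\n".join(lines)
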