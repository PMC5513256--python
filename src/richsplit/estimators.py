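"""Nonparametric species-richness estimators.

Abundance-based (one sample of counted individuals): bias-corrected Chao1,
first- and second-order jackknife (Jk1a/Jk2a) and the abundance-based coverage
estimator (ACE).  Incidence-based (presence/absence over m >= 2 sub-samples):
bias-corrected Chao2, first- and second-order incidence jackknife (Jk1i/Jk2i)
and the incidence-based coverage estimator (ICE).

All estimators add a non-negative rare-species correction to the observed
richness, so every estimate is >= s_obs.  The bias-corrected Chao forms are
defined for any configuration of singletons/doubletons (including none).
Formulas follow Chiu et al. (2014) and the EstimateS reference forms; Chao1
retains the (n-1)/n small-sample factor, which can be disabled to match
implementations that omit it.

Module-level ``_*_vec`` kernels evaluate the incidence estimators on arrays of
(s_obs, q1, q2) split statistics; the public scalar functions are thin
wrappers used for single data sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

from .sampling import AbundanceSample

__all__ = [
    "IncidenceSet",
    "EstimateResult",
    "chao1_bc",
    "chao2_bc",
    "jackknife_abundance",
    "jackknife_incidence",
    "ace",
    "ice",
    "ABUNDANCE_ESTIMATORS",
    "INCIDENCE_ESTIMATORS",
    "estimate",
]


@dataclass(frozen=True)
class IncidenceSet:
    """Species incidence over m sub-samples.

    ``incidence`` maps each observed species to the number of sub-samples
    (1..m) in which it occurs; ``q_counts[k]`` is the number of species found
    in exactly k sub-samples (q_1 = "uniques", q_2 = "duplicates").
    """

    m: int
    incidence: Mapping[Hashable, int]

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"incidence data requires m >= 2 sub-samples, got {self.m}")
        for sp, q in self.incidence.items():
            if int(q) != q or not (1 <= q <= self.m):
                raise ValueError(
                    f"incidence for species {sp!r} must be an integer in [1, {self.m}], got {q}"
                )

    @property
    def s_obs(self) -> int:
        return len(self.incidence)

    @property
    def q_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for q in self.incidence.values():
            out[q] = out.get(q, 0) + 1
        return out

    def q(self, k: int) -> int:
        return self.q_counts.get(k, 0)


@dataclass(frozen=True)
class EstimateResult:
    """A richness estimate together with the statistics it used."""

    estimator_id: str
    estimate: float
    s_obs: int
    size: int  # n (individuals) for abundance, m (sub-samples) for incidence
    rare_one: int  # f1 or q1
    rare_two: int  # f2 or q2
    fallback: bool = False


# ---------------------------------------------------------------------------
# vectorised kernels (array in, array out)

def _chao1_vec(s_obs, n, f1, f2, small_sample_correction=True):
    s_obs = np.asarray(s_obs, dtype=float)
    n = np.asarray(n, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    factor = (n - 1.0) / n if small_sample_correction else 1.0
    return s_obs + factor * f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def _chao2_vec(s_obs, m, q1, q2):
    s_obs = np.asarray(s_obs, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    return s_obs + (m - 1.0) / m * q1 * (q1 - 1.0) / (2.0 * (q2 + 1.0))


def _jk1_vec(s_obs, size, r1):
    s_obs = np.asarray(s_obs, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    return s_obs + r1 * (size - 1.0) / size


def _jk2_vec(s_obs, size, r1, r2):
    s_obs = np.asarray(s_obs, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    est = (
        s_obs
        + r1 * (2.0 * size - 3.0) / size
        - r2 * (size - 2.0) ** 2 / (size * (size - 1.0))
    )
    # the raw order-2 form can dip below the observed richness when doubletons
    # outnumber singletons; fewer species than observed is impossible, so the
    # estimate is floored at s_obs
    return np.maximum(est, s_obs)


def _ice_m2_vec(s_obs, q1, q2):
    """ICE on two sub-samples: all species are infrequent, m_infreq = 2.

    Falls back to bias-corrected Chao2 where coverage is zero (no duplicated
    species).  Returns (estimates, fallback_mask).
    """
    s_obs = np.asarray(s_obs, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    n_inf = q1 + 2.0 * q2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 1.0 - q1 / n_inf
        gamma2 = np.maximum((s_obs / c) * 2.0 * (2.0 * q2) / n_inf**2 - 1.0, 0.0)
        est = s_obs / c + (q1 / c) * gamma2
    bad = ~np.isfinite(est) | (c <= 0) | (n_inf <= 0)
    est = np.where(bad, _chao2_vec(s_obs, 2, q1, q2), est)
    return est, bad


# ---------------------------------------------------------------------------
# scalar estimators


def chao1_bc(sample: AbundanceSample, small_sample_correction: bool = True) -> EstimateResult:
    """Bias-corrected Chao1 abundance estimator.

    ``s_obs + (n-1)/n * f1 (f1 - 1) / (2 (f2 + 1))``; defined for all values
    of f1 and f2.  Set ``small_sample_correction=False`` to drop the (n-1)/n
    factor used by Chiu et al. (2014).
    """
    n = sample.n
    if n < 1:
        raise ValueError("empty sample")
    f1, f2 = sample.f(1), sample.f(2)
    est = float(_chao1_vec(sample.s_obs, n, f1, f2, small_sample_correction))
    return EstimateResult("chao1_bc", est, sample.s_obs, n, f1, f2)


def chao2_bc(inc: IncidenceSet) -> EstimateResult:
    """Bias-corrected Chao2 incidence estimator.

    ``s_obs + (m-1)/m * q1 (q1 - 1) / (2 (q2 + 1))``.
    """
    q1, q2 = inc.q(1), inc.q(2)
    est = float(_chao2_vec(inc.s_obs, inc.m, q1, q2))
    return EstimateResult("chao2_bc", est, inc.s_obs, inc.m, q1, q2)


def jackknife_abundance(sample: AbundanceSample, order: int = 1) -> EstimateResult:
    """Abundance-based jackknife estimator of order 1 or 2 (Jk1a / Jk2a)."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    n = sample.n
    if n < order + 1:
        raise ValueError(f"order-{order} jackknife requires n >= {order + 1}, got {n}")
    f1, f2 = sample.f(1), sample.f(2)
    if order == 1:
        est = float(_jk1_vec(sample.s_obs, n, f1))
    else:
        est = float(_jk2_vec(sample.s_obs, n, f1, f2))
    return EstimateResult(f"jk{order}a", est, sample.s_obs, n, f1, f2)


def jackknife_incidence(inc: IncidenceSet, order: int = 1) -> EstimateResult:
    """Incidence-based jackknife of order 1 or 2 (Jk1i / Jk2i).

    With two sub-samples the two orders coincide exactly: the second-order
    term carries a factor (m-2)^2 which vanishes at m = 2.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    q1, q2 = inc.q(1), inc.q(2)
    if order == 1:
        est = float(_jk1_vec(inc.s_obs, inc.m, q1))
    else:
        est = float(_jk2_vec(inc.s_obs, inc.m, q1, q2))
    return EstimateResult(f"jk{order}i", est, inc.s_obs, inc.m, q1, q2)


def ace(sample: AbundanceSample, rare_cutoff: int = 10) -> EstimateResult:
    """Abundance-based coverage estimator (ACE).

    Species with counts <= ``rare_cutoff`` form the rare group, whose sample
    coverage ``C = 1 - f1 / N_rare`` rescales the rare richness; a squared
    coefficient of variation term corrects for heterogeneity.  When coverage
    is zero (every rare species a singleton) the estimator is undefined and
    bias-corrected Chao1 is returned instead, flagged and warned.
    """
    n = sample.n
    if n < 1:
        raise ValueError("empty sample")
    f1, f2 = sample.f(1), sample.f(2)
    counts = sample.count_vector()
    rare = counts[counts <= rare_cutoff]
    s_rare = rare.size
    s_abund = int(sample.s_obs - s_rare)
    if s_rare == 0:
        return EstimateResult("ace", float(sample.s_obs), sample.s_obs, n, f1, f2)
    n_rare = int(rare.sum())
    coverage = 1.0 - f1 / n_rare
    if coverage <= 0.0 or n_rare < 2:
        warnings.warn(
            "ACE undefined (zero rare-class coverage); falling back to chao1_bc",
            RuntimeWarning,
            stacklevel=2,
        )
        cb = chao1_bc(sample)
        return EstimateResult("ace", cb.estimate, sample.s_obs, n, f1, f2, fallback=True)
    sum_kk1 = float(np.sum(rare * (rare - 1.0)))
    gamma2 = max((s_rare / coverage) * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    est = s_abund + s_rare / coverage + (f1 / coverage) * gamma2
    return EstimateResult("ace", float(est), sample.s_obs, n, f1, f2)


def ice(inc: IncidenceSet, infrequent_cutoff: int = 10) -> EstimateResult:
    """Incidence-based coverage estimator (ICE).

    Incidence analogue of ACE: species found in <= ``infrequent_cutoff``
    sub-samples form the infrequent group; coverage is ``1 - q1 / N_infreq``
    with ``N_infreq`` the total incidence of that group, and the heterogeneity
    term carries the sample-number correction ``m_infreq / (m_infreq - 1)``
    where ``m_infreq`` counts sub-samples containing at least one infrequent
    species.  Undefined configurations (zero coverage, or fewer than two
    sub-samples with infrequent species) fall back to bias-corrected Chao2.
    """
    q1, q2 = inc.q(1), inc.q(2)
    qc = inc.q_counts
    infreq = {k: v for k, v in qc.items() if k <= infrequent_cutoff}
    s_infreq = sum(infreq.values())
    s_freq = inc.s_obs - s_infreq
    if s_infreq == 0:
        return EstimateResult("ice", float(inc.s_obs), inc.s_obs, inc.m, q1, q2)
    n_infreq = sum(k * v for k, v in infreq.items())
    # m_infreq: sub-samples holding >= 1 infrequent species.  Incidence counts
    # alone do not identify which sub-samples those are; the standard
    # approximation m_infreq = min(m, N_infreq) is exact whenever infrequent
    # species cover all sub-samples (always the case at m = 2 with q2 > 0).
    m_infreq = min(inc.m, n_infreq)
    coverage = 1.0 - q1 / n_infreq if n_infreq > 0 else 0.0
    if coverage <= 0.0 or m_infreq <= 1:
        warnings.warn(
            "ICE undefined (zero infrequent-class coverage); falling back to chao2_bc",
            RuntimeWarning,
            stacklevel=2,
        )
        cb = chao2_bc(inc)
        return EstimateResult("ice", cb.estimate, inc.s_obs, inc.m, q1, q2, fallback=True)
    sum_kk1 = float(sum(k * (k - 1.0) * v for k, v in infreq.items()))
    gamma2 = max(
        (s_infreq / coverage)
        * (m_infreq / (m_infreq - 1.0))
        * sum_kk1
        / n_infreq**2
        - 1.0,
        0.0,
    )
    est = s_freq + s_infreq / coverage + (q1 / coverage) * gamma2
    return EstimateResult("ice", float(est), inc.s_obs, inc.m, q1, q2)


ABUNDANCE_ESTIMATORS = {
    "chao1_bc": chao1_bc,
    "jk1a": lambda s: jackknife_abundance(s, 1),
    "jk2a": lambda s: jackknife_abundance(s, 2),
    "ace": ace,
}

INCIDENCE_ESTIMATORS = {
    "chao2_bc": chao2_bc,
    "jk1i": lambda i: jackknife_incidence(i, 1),
    "jk2i": lambda i: jackknife_incidence(i, 2),
    "ice": ice,
}


def estimate(data, estimator_id: str) -> EstimateResult:
    """Dispatch to an estimator by id for either data kind."""
    if estimator_id in ABUNDANCE_ESTIMATORS:
        if not isinstance(data, AbundanceSample):
            raise TypeError(f"{estimator_id} requires abundance data")
        return ABUNDANCE_ESTIMATORS[estimator_id](data)
    if estimator_id in INCIDENCE_ESTIMATORS:
        if not isinstance(data, IncidenceSet):
            raise TypeError(f"{estimator_id} requires incidence data")
        return INCIDENCE_ESTIMATORS[estimator_id](data)
    raise ValueError(f"unknown estimator {estimator_id!r}")
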