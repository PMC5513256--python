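"""Bias / variance / mean-squared-error bookkeeping for estimator evaluation.

An estimator's accuracy against a known true richness S is summarised by its
MSE = Var + bias^2 over repeated samples.  For split-based estimates the
variance has two components: the variance of the aggregated estimate over
repeated draws from the assemblage, plus the mean over draws of the variance
across random partitions of each draw (law-of-total-variance decomposition).
Variances use the population (1/N) convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerformanceRecord",
    "mse_abundance",
    "mse_split",
    "proportionate_difference",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """Per-(assemblage, sample size, estimator) accuracy summary."""

    estimator_id: str
    bias: float
    variance: float
    mse: float
    n_draws: int
    n_splits: int = 0
    fallback_count: int = 0
    family: str = ""
    S: int = 0
    N: float = 0.0
    cv: float = 0.0
    n: int = 0
    s_mean: float = 0.0

    def __post_init__(self) -> None:
        expected = self.variance + self.bias**2
        scale = max(abs(self.mse), abs(expected), 1.0)
        if abs(self.mse - expected) > 1e-9 * scale:
            raise ValueError(
                f"mse must equal variance + bias^2 ({self.mse} vs {expected})"
            )


def _record(bias, variance, n_draws, n_splits, **meta) -> PerformanceRecord:
    return PerformanceRecord(
        estimator_id=meta.pop("estimator_id", ""),
        bias=float(bias),
        variance=float(variance),
        mse=float(variance + bias * bias),
        n_draws=int(n_draws),
        n_splits=int(n_splits),
        **meta,
    )


def mse_abundance(estimates, S_true: float, **meta) -> PerformanceRecord:
    """Bias, variance and MSE of per-draw estimates against true richness.

    ``bias = mean(estimates) - S_true``; variance over draws uses the
    population (1/N) convention; ``mse = variance + bias^2``.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("need at least 2 draws to estimate variance")
    bias = estimates.mean() - S_true
    variance = estimates.var()
    return _record(bias, variance, estimates.size, 0, **meta)


def mse_split(estimates, split_variances, S_true: float, **meta) -> PerformanceRecord:
    """MSE of split-based estimates with the two-component variance.

    ``estimates`` are the per-draw aggregates over random partitions and
    ``split_variances`` the per-draw variances across partitions; the total
    variance is ``Var(aggregates over draws) + mean(split_variances)``.
    """
    estimates = np.asarray(estimates, dtype=float)
    split_variances = np.asarray(split_variances, dtype=float)
    if estimates.shape != split_variances.shape:
        raise ValueError("estimates and split_variances must have equal length")
    if estimates.size < 2:
        raise ValueError("need at least 2 draws to estimate variance")
    if np.any(split_variances < 0):
        raise ValueError("split variances must be non-negative")
    bias = estimates.mean() - S_true
    variance = estimates.var() + split_variances.mean()
    n_splits = meta.pop("n_splits", 0)
    return _record(bias, variance, estimates.size, n_splits, **meta)


def proportionate_difference(mse_incidence: float, mse_abundance: float) -> float:
    """Proportionate MSE difference, (MSE_i - MSE_a) / min(MSE_i, MSE_a).

    Negative values mean the split incidence estimator is more accurate than
    its abundance counterpart.  Undefined when either MSE is zero (both
    estimators have converged); callers filter such cases.
    """
    if mse_incidence <= 0 or mse_abundance <= 0:
        raise ValueError("proportionate difference undefined for zero MSE")
    return (mse_incidence - mse_abundance) / min(mse_incidence, mse_abundance)
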