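"""Species-abundance distributions and ranked catch-probability assemblages.

A theoretical assemblage is described by its species richness ``S``, the mean
abundance per species and the coefficient of variation (CV) of per-species
abundance.  Four SAD families are supported: lognormal, log series, geometric
series and negative binomial.  Each family yields a ranked abundance vector
(most common species first) obtained by evaluating the family's
abundance-by-rank function — the inverse of its cumulative species
distribution — at ``S`` rank quantiles: midpoint ``(i - 1/2)/S`` by default,
or endpoint ``i/S`` with the rarest species at the numerical detectability
floor (see :func:`_rank_quantiles`).
Normalising the ranked abundances by total abundance gives the probability
that a randomly sampled individual belongs to each ranked species, which is
all that inverse-CDF sampling of individuals requires.

High CV means a few very common species and a long tail of rare ones; CV near
zero means a perfectly even community.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SADParams",
    "Assemblage",
    "lognormal_derived",
    "lognormal_ranked_weights",
    "series_params_from_cv",
    "catch_probabilities",
]

FAMILIES = ("lognormal", "log_series", "geometric", "negative_binomial")

_PROB_TOL = 1e-12


class InfeasibleSADError(ValueError):
    """Requested (family, S, cv) combination cannot be realised."""


def lognormal_derived(mean_abundance: float, cv: float) -> tuple[float, float]:
    """Log-scale parameters (mu, sigma) of a lognormal abundance distribution.

    Uses the moment identities ``sigma^2 = ln(1 + cv^2)`` and
    ``mu = ln(mean) - sigma^2 / 2`` so that ``exp(mu + sigma^2/2)`` equals the
    requested arithmetic mean abundance.
    """
    if mean_abundance <= 0:
        raise ValueError(f"mean_abundance must be positive, got {mean_abundance}")
    if cv <= 0:
        raise ValueError(f"cv must be positive, got {cv}")
    sigma2 = np.log1p(cv * cv)
    sigma = float(np.sqrt(sigma2))
    mu = float(np.log(mean_abundance) - sigma2 / 2.0)
    return mu, sigma


QUANTILE_CONVENTIONS = ("midpoint", "endpoint")


def _rank_quantiles(S: int, convention: str = "midpoint") -> np.ndarray:
    """Rank quantiles p_i at which the abundance-by-rank function is evaluated.

    ``midpoint``: p_i = (i - 0.5)/S, strictly inside (0, 1); symmetric between
    the common and rare halves of the assemblage and free of the inverse-CDF
    singularity at p = 1.

    ``endpoint``: p_i = i/S with the final quantile clipped to 1 - eps (float
    machine epsilon).  This places the rarest species at the numerical
    detectability floor: its catch probability is positive but so small that
    it is essentially never seen at survey-scale sampling effort, while a
    near-census of a small population can still find it.  Sweeps default to
    this convention because the estimator-comparison thresholds arise from
    exactly this barely-detectable rare tail.
    """
    if convention == "midpoint":
        return (np.arange(1, S + 1) - 0.5) / S
    if convention == "endpoint":
        p = np.arange(1, S + 1) / S
        return np.minimum(p, 1.0 - np.finfo(float).eps)
    raise ValueError(
        f"convention must be one of {QUANTILE_CONVENTIONS}, got {convention!r}"
    )


def lognormal_ranked_weights(
    S: int, sigma: float, convention: str = "midpoint"
) -> np.ndarray:
    """Unnormalised ranked abundances of a lognormal assemblage.

    ``w_i = exp(-sigma * sqrt(2) * erfinv(2 p_i - 1))`` at the rank quantiles
    ``p_i`` (see :func:`_rank_quantiles`); rank 1 is the most common species.
    The location parameter mu only rescales the vector and is omitted.
    """
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    p = _rank_quantiles(S, convention)
    if np.any(p <= 0.0) or np.any(p >= 1.0):  # pragma: no cover - convention bug
        raise AssertionError("rank quantiles must lie strictly inside (0, 1)")
    return np.exp(-sigma * np.sqrt(2.0) * special.erfinv(2.0 * p - 1.0))


def _geometric_ranked_weights(S: int, x: float) -> np.ndarray:
    # Ranked form of the geometric series: abundance decays by a constant
    # factor x per rank.
    return x ** np.arange(S, dtype=float)


def _log_series_ranked_weights(
    S: int, x: float, convention: str = "midpoint"
) -> np.ndarray:
    """Ranked abundances for a log-series assemblage.

    The log-series SAD puts ``alpha x^n / n`` species at abundance ``n``.  Its
    continuous relaxation has species-density proportional to ``x^t / t`` on
    ``t >= 1``, whose upper tail integral is the exponential integral
    ``E1(lambda t)`` with ``lambda = -ln x``.  The abundance of the species at
    rank quantile ``p`` (common species first) solves
    ``E1(lambda w) = p * E1(lambda)``.
    """
    lam = -np.log(x)
    total = special.exp1(lam)
    p = _rank_quantiles(S, convention)
    targets = p * total

    def tail(t: float, target: float) -> float:
        return special.exp1(lam * t) - target

    weights = np.empty(S)
    hi = 1.0
    # E1 is strictly decreasing, so each root is bracketed in [1, hi].
    for i, target in enumerate(targets):
        while tail(hi, target) > 0:
            hi *= 2.0
            if hi > 1e18:  # pragma: no cover - x numerically too close to 1
                raise InfeasibleSADError("log-series tail does not converge")
        weights[i] = optimize.brentq(tail, 1.0, hi, args=(target,), xtol=1e-12, rtol=1e-14)
        hi = max(hi, weights[i])
    return weights


def _negative_binomial_ranked_weights(
    S: int, mean: float, cv: float, convention: str = "midpoint"
) -> np.ndarray:
    # Gamma relaxation of the negative binomial: matching mean and variance
    # gives shape 1/cv^2 and scale mean*cv^2, a continuous quantile function
    # free of the zero-abundance ties of the discrete inverse CDF.
    shape = 1.0 / (cv * cv)
    scale = mean * cv * cv
    p = _rank_quantiles(S, convention)
    return stats.gamma.ppf(1.0 - p, a=shape, scale=scale)


def _vector_cv(w: np.ndarray) -> float:
    m = w.mean()
    return float(np.sqrt(np.mean((w - m) ** 2)) / m)


def series_params_from_cv(
    family: str, S: int, mean_abundance: float, cv: float
) -> dict[str, float]:
    """Family parameters reproducing a target ranked-abundance CV.

    For the geometric and log series the decay parameter ``x`` is found by
    root-finding so that the length-``S`` ranked weight vector has coefficient
    of variation ``cv`` (to 1e-6 or better).  For the negative binomial the
    moment mapping is closed form: ``r = mean^2/(var - mean)``,
    ``p = mean/var`` with ``var = (cv * mean)^2``.

    Raises
    ------
    InfeasibleSADError
        If no parameter in the family attains the requested cv at this S,
        with the attainable range in the message.
    """
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if mean_abundance <= 0 or cv <= 0:
        raise ValueError("mean_abundance and cv must be positive")

    if family == "negative_binomial":
        var = (cv * mean_abundance) ** 2
        if var <= mean_abundance:
            raise InfeasibleSADError(
                "negative binomial requires variance > mean: need "
                f"cv > {1.0 / np.sqrt(mean_abundance):.6g} at mean {mean_abundance}"
            )
        r = mean_abundance**2 / (var - mean_abundance)
        p = mean_abundance / var
        return {"r": float(r), "p": float(p)}

    if family == "geometric":
        weight_fn = _geometric_ranked_weights
    elif family == "log_series":
        weight_fn = _log_series_ranked_weights
    else:
        raise ValueError(f"unknown series family {family!r}")

    lo, hi = 1e-9, 1.0 - 1e-9
    # cv of the ranked vector decreases as x -> 1 (evenness) for both series.
    cv_lo, cv_hi = _vector_cv(weight_fn(S, lo)), _vector_cv(weight_fn(S, hi))
    cv_min, cv_max = min(cv_lo, cv_hi), max(cv_lo, cv_hi)
    if not (cv_min <= cv <= cv_max):
        raise InfeasibleSADError(
            f"{family} with S={S} attains cv in [{cv_min:.6g}, {cv_max:.6g}], "
            f"requested {cv}"
        )

    def objective(x: float) -> float:
        return _vector_cv(weight_fn(S, x)) - cv

    x = optimize.brentq(objective, lo, hi, xtol=1e-14, rtol=1e-15)
    out = {"x": float(x)}
    if family == "log_series":
        # alpha follows from normalisation: S = alpha * ln(1/(1-x)).
        out["alpha"] = float(S / -np.log1p(-x))
    else:
        # first term of the series from S = a / (1 - x).
        out["a"] = float(S * (1.0 - x))
    return out


@dataclass(frozen=True)
class SADParams:
    """Parameters of a theoretical species assemblage.

    Attributes
    ----------
    family : str
        One of ``lognormal``, ``log_series``, ``geometric``,
        ``negative_binomial``.
    S : int
        True species richness of the assemblage.
    mean_abundance : float
        Mean number of individuals per species; total abundance is
        ``N = S * mean_abundance``.
    cv : float
        Coefficient of variation of per-species abundance.
    derived : dict
        Family-specific parameters: ``(mu, sigma)`` for lognormal,
        ``(alpha, x)`` for log series, ``(a, x)`` for geometric,
        ``(r, p)`` for negative binomial.
    """

    family: str
    S: int
    mean_abundance: float
    cv: float
    derived: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if self.mean_abundance <= 0:
            raise ValueError("mean_abundance must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        for key in ("x", "p"):
            if key in self.derived and not (0.0 < self.derived[key] < 1.0):
                raise ValueError(f"derived parameter {key} must lie in (0, 1)")

    @property
    def N(self) -> float:
        """Total abundance of the statistical population."""
        return self.S * self.mean_abundance

    @classmethod
    def create(
        cls, family: str, S: int, mean_abundance: float, cv: float
    ) -> "SADParams":
        """Build params with the family's derived parameters filled in."""
        if family == "lognormal":
            mu, sigma = lognormal_derived(mean_abundance, cv)
            derived: dict[str, float] = {"mu": mu, "sigma": sigma}
        else:
            derived = series_params_from_cv(family, S, mean_abundance, cv)
        return cls(family, int(S), float(mean_abundance), float(cv), derived)


@dataclass(frozen=True)
class Assemblage:
    """Ranked catch probabilities of an assemblage, ready for sampling.

    ``probs[i]`` is the probability that a sampled individual belongs to the
    species of rank ``i + 1`` (rank 1 = most common); ``cumprobs`` is its
    cumulative sum used for inverse-CDF lookup, and ``abundances`` the
    expected (real-valued) per-species abundances ``probs * N``.
    """

    params: SADParams
    probs: np.ndarray
    cumprobs: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size != self.params.S:
            raise ValueError("probs must be a vector of length S")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError("probs must sum to 1")
        if np.any(np.diff(probs) > 1e-12):
            raise ValueError("probs must be non-increasing over rank")
        cum = np.asarray(self.cumprobs, dtype=float)
        if np.any(np.diff(cum) < -1e-15) or abs(cum[-1] - 1.0) > _PROB_TOL:
            raise ValueError("cumprobs must be non-decreasing with final element 1")

    @property
    def S(self) -> int:
        return self.params.S

    def to_tsv(self, path) -> None:
        """Write ranked probabilities as TSV (rank, probability, expected_abundance)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tprobability\texpected_abundance\n")
            for i, (p, b) in enumerate(zip(self.probs, self.abundances), start=1):
                fh.write(f"{i}\t{float(p)!r}\t{float(b)!r}\n")

    @classmethod
    def from_tsv(cls, path, params: SADParams | None = None) -> "Assemblage":
        """Read an assemblage written by :meth:`to_tsv`.

        If ``params`` is omitted, a minimal lognormal placeholder carrying only
        S and the implied mean abundance is attached.
        """
        ranks, probs, abund = [], [], []
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip().split("\t")
            if header != ["rank", "probability", "expected_abundance"]:
                raise ValueError(f"unexpected assemblage header {header}")
            for line in fh:
                r, p, b = line.strip().split("\t")
                ranks.append(int(r))
                probs.append(float(p))
                abund.append(float(b))
        probs_arr = np.asarray(probs)
        abund_arr = np.asarray(abund)
        if params is None:
            S = len(probs)
            params = SADParams(
                "lognormal", S, float(abund_arr.sum() / S), _vector_cv(abund_arr) or 1e-9,
                {"mu": 0.0, "sigma": 0.0},
            )
        return cls(params, probs_arr, np.cumsum(probs_arr), abund_arr)


def catch_probabilities(
    params: SADParams, convention: str = "midpoint"
) -> Assemblage:
    """Ranked catch-probability distribution of an assemblage.

    The family's ranked weight vector is normalised to sum to one; expected
    per-species abundances are the probabilities scaled by total abundance N.
    ``convention`` selects the rank quantiles (see :func:`_rank_quantiles`):
    ``midpoint`` is symmetric and keeps every species detectable, ``endpoint``
    puts the rarest species at the numerical detectability floor.  The series
    decay parameter x is always calibrated on the midpoint vector, so the cv
    of an endpoint assemblage can differ slightly from the nominal value.
    """
    derived = dict(params.derived)
    if params.family == "lognormal":
        if "sigma" not in derived:
            _, sigma = lognormal_derived(params.mean_abundance, params.cv)
        else:
            sigma = derived["sigma"]
        w = lognormal_ranked_weights(params.S, sigma, convention)
    elif params.family == "geometric":
        x = derived.get("x")
        if x is None:
            x = series_params_from_cv(
                "geometric", params.S, params.mean_abundance, params.cv
            )["x"]
        w = _geometric_ranked_weights(params.S, x)  # rank function; no quantiles
    elif params.family == "log_series":
        x = derived.get("x")
        if x is None:
            x = series_params_from_cv(
                "log_series", params.S, params.mean_abundance, params.cv
            )["x"]
        w = _log_series_ranked_weights(params.S, x, convention)
    elif params.family == "negative_binomial":
        w = _negative_binomial_ranked_weights(
            params.S, params.mean_abundance, params.cv, convention
        )
    else:  # pragma: no cover - guarded by SADParams
        raise ValueError(f"unknown family {params.family!r}")

    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError(f"degenerate ranked weights for {params}")
    probs = w / w.sum()
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return Assemblage(params, probs, cum, probs * params.N)
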