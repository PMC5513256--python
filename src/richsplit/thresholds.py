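"""Critical sample-size-to-richness ratios and the estimator-recommendation rule.

Above a critical ratio (n/s)_C of sample size to observed richness, the
split-sample incidence estimator out-performs (in MSE) its abundance-based
counterpart.  The critical ratio is located by binning sweep assemblages by
n/s and finding the point beyond which the proportionate MSE difference is
negative in more than half the assemblages (mid-criterion) or in nearly all
of them (edge-criterion, >= 95%).  Across the CV grid the critical ratios
follow a power law (n/s)_C = a * CV^b, and across population abundance N a
cubic polynomial; the fitted curves drive the recommendation rule:

* CV > 0.65: candidate pair is split Jackknife1i/2i vs. abundance Jackknife1a
* CV < 0.65: candidate pair is split Chao2 vs. abundance Chao1
* if n/s_obs exceeds the predicted (n/s)_C, split; otherwise stay with the
  abundance estimator on the unsplit sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .performance import proportionate_difference
from .sampling import AbundanceSample

__all__ = [
    "PAIRS",
    "CriticalRatio",
    "ThresholdModel",
    "pair_differences",
    "critical_ratio",
    "fit_power_law",
    "fit_poly_N",
    "recommend",
    "split_estimator_crossover",
    "Recommendation",
    "estimate_cv_from_sample",
]

#: estimator pair -> (split incidence estimator, abundance counterpart)
PAIRS = {
    "chao2_vs_chao1": ("chao2_bc", "chao1_bc"),
    "jk_i_vs_jk1a": ("jk1i", "jk1a"),
}

CV_BOUNDARY = 0.65


def pair_differences(
    sweep: pd.DataFrame, pair: str, k: int = 2, converged_mse: float = 1.0
) -> pd.DataFrame:
    """Per-assemblage proportionate MSE differences for an estimator pair.

    Returns columns ``ratio`` (n / mean observed richness), ``diff`` (the
    proportionate MSE difference, negative when splitting wins) plus the
    assemblage descriptors.  Assemblages where both estimators have
    effectively converged — both MSEs below ``converged_mse`` (default one
    squared species, i.e. each estimator within a fraction of a species of
    the truth) — are excluded: there the sign of the difference reflects
    sub-species rounding of a moot comparison, not estimator quality.
    Zero MSEs are always excluded (the difference is undefined).
    """
    inc_id, ab_id = PAIRS[pair]
    inc = sweep[(sweep["estimator"] == inc_id) & (sweep["k"] == k)]
    ab = sweep[sweep["estimator"] == ab_id]
    merged = inc.merge(
        ab, on="asm_index", suffixes=("_inc", "_ab"), validate="one_to_one"
    )
    merged = merged[(merged["mse_inc"] > 0) & (merged["mse_ab"] > 0)]
    merged = merged[
        (merged["mse_inc"] >= converged_mse) | (merged["mse_ab"] >= converged_mse)
    ].copy()
    merged["diff"] = (merged["mse_inc"] - merged["mse_ab"]) / np.minimum(
        merged["mse_inc"], merged["mse_ab"]
    )
    merged["ratio"] = merged["n_inc"] / merged["s_mean_inc"]
    out = merged[
        ["asm_index", "ratio", "diff", "family_inc", "S_inc", "N_inc", "cv_inc", "n_inc"]
    ]
    return out.rename(
        columns={
            "family_inc": "family", "S_inc": "S", "N_inc": "N",
            "cv_inc": "cv", "n_inc": "n",
        }
    )


@dataclass(frozen=True)
class CriticalRatio:
    """A located (n/s)_C crossing, or a no-crossing sentinel."""

    value: float  # nan when no crossing
    criterion: str
    n_assemblages: int
    bin_fractions: tuple = ()

    @property
    def crossed(self) -> bool:
        return np.isfinite(self.value)


def critical_ratio(
    ratios,
    diffs,
    criterion: str = "mid",
    n_bins: int = 10,
) -> CriticalRatio:
    """Locate the critical n/s ratio from per-assemblage MSE differences.

    Assemblages are placed into ``n_bins`` equal-count bins of n/s.  The
    mid-criterion is the centre of the smallest bin from which the fraction
    of negative differences exceeds 0.5 in that bin and in every larger bin;
    the edge-criterion uses a 0.95 fraction.  Returns a no-crossing sentinel
    (``value = nan``) when the criterion is never satisfied.
    """
    if criterion not in ("mid", "edge"):
        raise ValueError(f"criterion must be 'mid' or 'edge', got {criterion!r}")
    thresh = 0.5 if criterion == "mid" else 0.95
    ratios = np.asarray(ratios, dtype=float)
    diffs = np.asarray(diffs, dtype=float)
    if ratios.size != diffs.size:
        raise ValueError("ratios and diffs must have equal length")
    if ratios.size < 20:
        raise ValueError(f"need >= 20 assemblages, got {ratios.size}")

    quantiles = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(ratios, quantiles)
    edges = np.unique(edges)
    if edges.size < 3:
        raise ValueError("n/s ratios too degenerate to bin")
    idx = np.clip(np.searchsorted(edges, ratios, side="right") - 1, 0, edges.size - 2)

    nb = edges.size - 1
    frac_neg = np.empty(nb)
    for b in range(nb):
        mask = idx == b
        frac_neg[b] = (diffs[mask] < 0).mean() if mask.any() else np.nan
    ok = frac_neg > thresh

    value = np.nan
    # smallest bin from which the criterion holds in every larger bin
    for b in range(nb):
        if np.all(ok[b:]):
            value = 0.5 * (edges[b] + edges[b + 1])
            break
    return CriticalRatio(float(value), criterion, ratios.size, tuple(frac_neg))


def fit_power_law(cvs, ratios) -> tuple[float, float, float]:
    """Nonlinear least-squares fit of (n/s)_C = a * cv^b.

    Initialised from a log-log linear regression.  Returns ``(a, b,
    residual_norm)``; raises on non-convergence with the initial guess and
    data sizes in the message.
    """
    cvs = np.asarray(cvs, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    mask = np.isfinite(cvs) & np.isfinite(ratios)
    cvs, ratios = cvs[mask], ratios[mask]
    if cvs.size < 3:
        raise ValueError(f"need >= 3 finite points, got {cvs.size}")
    if np.any(cvs <= 0) or np.any(ratios <= 0):
        raise ValueError("power-law fit requires positive cv and ratio values")

    slope, intercept = np.polyfit(np.log(cvs), np.log(ratios), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.power(x, b), cvs, ratios, p0=p0, maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - hard to trigger
        raise RuntimeError(
            f"power-law fit failed to converge (init {p0}, {cvs.size} points)"
        ) from err
    a, b = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(ratios - a * cvs**b))
    return a, b, resid


def fit_poly_N(Ns, ratios) -> np.ndarray:
    """Ordinary least-squares cubic fit of (n/s)_C against N.

    Returns degree-3 coefficients, highest power first (numpy polyfit order).
    """
    Ns = np.asarray(Ns, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if Ns.size < 4:
        raise ValueError(f"need >= 4 points for a cubic, got {Ns.size}")
    if np.unique(Ns).size < 4:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (fewer than 4 distinct N values)"
        )
    # fit in a scaled domain (N spans orders of magnitude) and convert back
    poly = np.polynomial.Polynomial.fit(Ns, ratios, deg=3).convert()
    return poly.coef[::-1]  # highest power first


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted critical-ratio curve (n/s)_C = a * cv^b for one estimator pair."""

    estimator_pair: str
    criterion: str
    N_range: tuple
    a: float
    b: float
    fit_points: tuple = ()  # ((cv, critical_ratio), ...)
    poly_N: tuple | None = None  # degree-3 coefficients, highest power first

    def __post_init__(self) -> None:
        if self.estimator_pair not in PAIRS:
            raise ValueError(f"estimator_pair must be one of {tuple(PAIRS)}")
        if self.a <= 0:
            raise ValueError("power-law prefactor a must be positive")
        if not self.fit_points:
            raise ValueError("fit_points must be non-empty")

    def predict(self, cv: float) -> float:
        """Predicted critical n/s ratio at a given cv."""
        return float(self.a * cv**self.b)

    @classmethod
    def fit(
        cls,
        sweep: pd.DataFrame,
        pair: str,
        criterion: str = "mid",
        n_bins: int = 10,
        k: int = 2,
        N_range: tuple | None = None,
    ) -> "ThresholdModel":
        """Extract per-cv critical ratios from a sweep and fit the power law."""
        diffs = pair_differences(sweep, pair, k=k)
        if N_range is not None:
            diffs = diffs[(diffs["N"] >= N_range[0]) & (diffs["N"] <= N_range[1])]
        else:
            N_range = (float(diffs["N"].min()), float(diffs["N"].max()))
        points = []
        for cv, group in diffs.groupby("cv"):
            if len(group) < 20:
                continue
            cr = critical_ratio(group["ratio"], group["diff"], criterion, n_bins)
            if cr.crossed:
                points.append((float(cv), cr.value))
        if len(points) < 3:
            raise ValueError(
                f"only {len(points)} cv cells produced a crossing; cannot fit"
            )
        a, b, _ = fit_power_law([p[0] for p in points], [p[1] for p in points])
        return cls(pair, criterion, tuple(N_range), a, b, tuple(points))

    # -- plain-text serialisation -------------------------------------------

    def to_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"pair = {self.estimator_pair}\n")
            fh.write(f"criterion = {self.criterion}\n")
            fh.write(f"N_low = {self.N_range[0]!r}\n")
            fh.write(f"N_high = {self.N_range[1]!r}\n")
            fh.write(f"a = {self.a!r}\n")
            fh.write(f"b = {self.b!r}\n")
            pts = ";".join(f"{cv!r},{r!r}" for cv, r in self.fit_points)
            fh.write(f"fit_points = {pts}\n")
            if self.poly_N is not None:
                fh.write(f"poly_N = {','.join(repr(c) for c in self.poly_N)}\n")

    @classmethod
    def from_text(cls, path) -> "ThresholdModel":
        kv: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        points = tuple(
            tuple(float(x) for x in item.split(","))
            for item in kv["fit_points"].split(";")
            if item
        )
        poly = None
        if "poly_N" in kv:
            poly = tuple(float(x) for x in kv["poly_N"].split(","))
        return cls(
            kv["pair"],
            kv["criterion"],
            (float(kv["N_low"]), float(kv["N_high"])),
            float(kv["a"]),
            float(kv["b"]),
            points,
            poly,
        )


@dataclass(frozen=True)
class Recommendation:
    """Outcome of the estimator-recommendation rule for one sample."""

    estimator_id: str
    use_splitting: bool
    k: int
    branch: str  # "chao" (cv <= 0.65) or "jackknife" (cv > 0.65)
    cv_hat: float
    ratio: float  # n / s_obs
    threshold: float  # predicted (n/s)_C
    note: str = ""

    def describe(self) -> str:
        how = f"{self.k}-way split" if self.use_splitting else "unsplit sample"
        return (
            f"{self.estimator_id} on the {how} "
            f"(cv_hat={self.cv_hat:.3f}, n/s={self.ratio:.1f}, "
            f"(n/s)_C={self.threshold:.1f})"
        )


def recommend(
    n: int,
    s_obs: int,
    N_hat: float,
    cv_hat: float,
    chao_model: ThresholdModel,
    jk_model: ThresholdModel,
) -> Recommendation:
    """Recommend an estimator for a sample via the threshold rule.

    Parameters
    ----------
    n, s_obs : int
        Sample size and observed richness.
    N_hat, cv_hat : float
        Estimated population abundance and abundance coefficient of variation.
    chao_model, jk_model : ThresholdModel
        Fitted critical-ratio curves for the Chao2-vs-Chao1 and
        Jackknife1i/2i-vs-Jackknife1a pairs.
    """
    if n <= 0 or s_obs <= 0 or N_hat <= 0 or cv_hat < 0:
        raise ValueError("n, s_obs, N_hat must be positive and cv_hat non-negative")
    note = ""
    if cv_hat == CV_BOUNDARY:
        note = "cv_hat exactly at the 0.65 boundary; using the Chao branch"
        warnings.warn(note, RuntimeWarning, stacklevel=2)
    if cv_hat > CV_BOUNDARY:
        branch, model = "jackknife", jk_model
        split_id, abundance_id = "jk1i", "jk1a"
    else:
        branch, model = "chao", chao_model
        split_id, abundance_id = "chao2_bc", "chao1_bc"
    threshold = model.predict(cv_hat)
    ratio = n / s_obs
    use_split = ratio > threshold
    return Recommendation(
        estimator_id=split_id if use_split else abundance_id,
        use_splitting=use_split,
        k=2 if use_split else 0,
        branch=branch,
        cv_hat=float(cv_hat),
        ratio=float(ratio),
        threshold=float(threshold),
        note=note,
    )


def split_estimator_crossover(
    sweep: pd.DataFrame,
    chao_model: ThresholdModel | None = None,
    jk_model: ThresholdModel | None = None,
    k: int = 2,
    min_assemblages: int = 20,
) -> float:
    """CV at which the best split estimator switches from Chao2 to Jackknife.

    Restricts each CV cell to assemblages whose n/s ratio exceeds the fitted
    mid-criterion of both threshold pairs (the regime where splitting is
    recommended), compares the mean MSE of the 2-split Chao2 and incidence
    jackknife there, and returns the midpoint of the grid interval bracketing
    the stable switch from Chao2 wins to jackknife wins (nan when either
    estimator never wins).
    """
    if chao_model is None:
        chao_model = ThresholdModel.fit(sweep, "chao2_vs_chao1", "mid")
    if jk_model is None:
        jk_model = ThresholdModel.fit(sweep, "jk_i_vs_jk1a", "mid")

    chao = sweep[(sweep["estimator"] == "chao2_bc") & (sweep["k"] == k)]
    jk = sweep[(sweep["estimator"] == "jk1i") & (sweep["k"] == k)]
    merged = chao.merge(jk, on="asm_index", suffixes=("_chao", "_jk"), validate="one_to_one")
    merged["ratio"] = merged["n_chao"] / merged["s_mean_chao"]

    winners: dict[float, str] = {}
    for cv, group in merged.groupby("cv_chao"):
        threshold = max(chao_model.predict(cv), jk_model.predict(cv))
        sub = group[group["ratio"] > threshold]
        if len(sub) < min_assemblages:
            continue
        winners[float(cv)] = (
            "chao2" if sub["mse_chao"].mean() <= sub["mse_jk"].mean() else "jk"
        )
    cvs = sorted(winners)
    jk_wins = [cv for cv in cvs if winners[cv] == "jk"]
    chao_wins = [cv for cv in cvs if winners[cv] == "chao2"]
    if not jk_wins or not chao_wins:
        return float("nan")
    # midpoint between the last grid point Chao2 wins and the first the
    # jackknife wins; with a noisy, non-monotone winner sequence this is the
    # centre of the contested region
    return 0.5 * (max(chao_wins) + min(jk_wins))


def estimate_cv_from_sample(sample: AbundanceSample) -> float:
    """Coefficient of variation of the observed per-species counts.

    Population (1/s) standard deviation over the species observed at least
    once, divided by their mean count.  A rough plug-in for the assemblage cv
    used by the recommendation rule.
    """
    if sample.s_obs < 2:
        raise ValueError("cv estimation requires at least 2 observed species")
    counts = sample.count_vector().astype(float)
    return float(counts.std() / counts.mean())
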