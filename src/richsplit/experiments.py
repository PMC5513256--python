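"""Scenario sweeps: estimator accuracy over randomly drawn assemblages.

A sweep draws many theoretical assemblages per CV grid point (population
abundance N, richness S and sample size n drawn from configured laws),
repeatedly samples each assemblage, evaluates abundance-based estimators on
each sample and incidence-based estimators on repeated random splits of each
sample, and records bias / variance / MSE per (assemblage, estimator).

Default scenario parameters reproduce the main lognormal study design:
N uniform on [1e3, 1e5]; S uniform on {2..min(500, round(N/200))} so richness
scales with population size; n uniform on [300, 5000] rejected until n < N;
CV grid 0.15, 0.25, ..., 1.15; 6000 assemblages per CV, 1000 draws per
assemblage and 300 random 2-way splits per draw.  ``ScenarioConfig.scaled``
shrinks replicate counts proportionally for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimators import _chao1_vec, _jk1_vec, _jk2_vec
from .performance import PerformanceRecord, mse_abundance, mse_split
from .sad import InfeasibleSADError, SADParams, catch_probabilities
from .sampling import as_rng
from .splitting import _estimates_from_q, _split_counts, _split_stats_k2

__all__ = [
    "ScenarioConfig",
    "MAIN_SWEEP",
    "SMALL_POPULATION_SWEEP",
    "draw_scenario_assemblage",
    "run_sweep",
    "design_sample_fractions",
]

_ABUNDANCE_IDS = ("chao1_bc", "jk1a", "jk2a", "ace")
_INCIDENCE_IDS = ("chao2_bc", "jk1i", "jk2i", "ice")

RESULT_COLUMNS = [
    "family", "S", "N", "cv", "n", "estimator", "bias", "variance", "mse",
    "n_draws", "n_splits", "fallbacks", "k", "s_mean", "asm_index",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation sweep.

    Attributes
    ----------
    sad_families : tuple of str
    n_assemblages : int
        Assemblages drawn per (family, cv) cell.
    N_range : (low, high)
        Population abundance, drawn uniformly.
    S_rule : ("abundance_scaled", (lo, hi)) | ("uniform", (lo, hi)) | callable
        ``abundance_scaled`` draws S uniformly on {lo..min(hi, round(N/200))};
        ``uniform`` ignores N; a callable receives (N, rng) and returns S.
    n_rule : ("absolute", (lo, hi)) | ("fraction", (lo, hi))
        Sample size law: uniform on [lo, hi] individuals with rejection until
        n < N, or a uniform fraction of N (1.0 = full census allowed).
    cv_grid : tuple of float
    n_draws : int
        Repeated samples per assemblage.
    n_splits : int
        Random partitions per sample for the splitting method.
    k_splits : tuple of int
        Partition arities to evaluate (2 is the recommended method).
    estimators : tuple of str
        Which of the eight estimators to evaluate.
    aggregate : {"mean", "median"}
        Aggregation of per-split estimates.
    quantile_convention : {"endpoint", "midpoint"}
        Rank-quantile convention for the ranked-abundance construction.  The
        default ``endpoint`` evaluates abundance-by-rank at i/S (rarest
        species at the numerical detectability floor), which is the
        construction whose barely-detectable rare tail produces the
        estimator-comparison thresholds; ``midpoint`` keeps every species
        comfortably detectable.
    seed : int
    """

    sad_families: tuple = ("lognormal",)
    n_assemblages: int = 6000
    N_range: tuple = (1e3, 1e5)
    S_rule: tuple | Callable = ("abundance_scaled", (2, 500))
    n_rule: tuple = ("absolute", (300, 5000))
    cv_grid: tuple = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.05, 1.15)
    n_draws: int = 1000
    n_splits: int = 300
    k_splits: tuple = (2,)
    estimators: tuple = _ABUNDANCE_IDS + _INCIDENCE_IDS
    aggregate: str = "mean"
    quantile_convention: str = "endpoint"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assemblages < 1 or self.n_draws < 2 or self.n_splits < 1:
            raise ValueError("n_assemblages >= 1, n_draws >= 2, n_splits >= 1 required")
        lo, hi = self.N_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid N_range {self.N_range}")
        for e in self.estimators:
            if e not in _ABUNDANCE_IDS + _INCIDENCE_IDS:
                raise ValueError(f"unknown estimator {e!r}")
        for k in self.k_splits:
            if k < 2:
                raise ValueError("split arities must be >= 2")
        for f in self.sad_families:
            if f not in ("lognormal", "log_series", "geometric", "negative_binomial"):
                raise ValueError(f"unknown SAD family {f!r}")
        if self.quantile_convention not in ("midpoint", "endpoint"):
            raise ValueError(
                f"unknown quantile convention {self.quantile_convention!r}"
            )

    def scaled(self, scale: float) -> "ScenarioConfig":
        """Proportionally shrink replicate counts (for desk-scale runs)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return dataclasses.replace(
            self,
            n_assemblages=max(1, round(self.n_assemblages * scale)),
            n_draws=max(2, round(self.n_draws * scale)),
            n_splits=max(1, round(self.n_splits * scale)),
        )


#: Main lognormal sweep at full study scale.
MAIN_SWEEP = ScenarioConfig()

#: Small-population sweep: 1%-100% of N sampled, all four SAD families.
SMALL_POPULATION_SWEEP = ScenarioConfig(
    sad_families=("lognormal", "log_series", "geometric", "negative_binomial"),
    n_assemblages=10000,
    N_range=(100, 1000),
    S_rule=("uniform", (2, 20)),
    n_rule=("fraction", (0.01, 1.0)),
    n_draws=500,
    n_splits=300,
)


def _draw_S(config: ScenarioConfig, N: float, rng: np.random.Generator) -> int:
    rule = config.S_rule
    if callable(rule):
        return int(rule(N, rng))
    kind, (lo, hi) = rule
    if kind == "abundance_scaled":
        s_max = int(min(hi, max(lo, round(N / 200.0))))
        return int(rng.integers(lo, s_max + 1))
    if kind == "uniform":
        return int(rng.integers(lo, hi + 1))
    raise ValueError(f"unknown S_rule {rule!r}")


def draw_scenario_assemblage(
    config: ScenarioConfig, cv: float, rng, family: str = "lognormal"
) -> tuple[SADParams, int]:
    """Draw one (assemblage parameters, sample size) pair for a sweep cell.

    Redraws on parameter combinations the family cannot realise at the
    requested cv (e.g. a geometric series at S = 2 cannot exceed cv = 1).
    """
    rng = as_rng(rng)
    kind, (lo, hi) = config.n_rule
    for _ in range(1000):
        N = float(rng.uniform(*config.N_range))
        S = _draw_S(config, N, rng)
        if kind == "absolute":
            n = int(round(rng.uniform(lo, hi)))
            tries = 0
            while n >= N:
                n = int(round(rng.uniform(lo, hi)))
                tries += 1
                if tries > 10000:
                    raise ValueError("n_rule incompatible with N_range (n < N unattainable)")
        elif kind == "fraction":
            n = int(round(rng.uniform(lo, hi) * N))
            n = max(n, max(config.k_splits), 2)
        else:
            raise ValueError(f"unknown n_rule {config.n_rule!r}")
        try:
            params = SADParams.create(family, S, N / S, cv)
        except InfeasibleSADError:
            continue  # e.g. cv out of the family's range at this S; redraw
        return params, n
    raise InfeasibleSADError(
        f"could not draw a feasible {family} assemblage at cv={cv} "
        f"within 1000 attempts"
    )


def _abundance_stats(cnt_mat: np.ndarray, rare_cutoff: int = 10):
    """Vectorised per-draw sample statistics from a (n_draws, S) count matrix."""
    pos = cnt_mat > 0
    s_obs = pos.sum(axis=1)
    f1 = (cnt_mat == 1).sum(axis=1)
    f2 = (cnt_mat == 2).sum(axis=1)
    rare = pos & (cnt_mat <= rare_cutoff)
    s_rare = rare.sum(axis=1)
    n_rare = np.where(rare, cnt_mat, 0).sum(axis=1)
    sum_kk1 = np.where(rare, cnt_mat * (cnt_mat - 1), 0).sum(axis=1)
    return s_obs, f1, f2, s_rare, n_rare, sum_kk1


def _ace_vec(s_obs, n, f1, f2, s_rare, n_rare, sum_kk1):
    """Vectorised ACE with bias-corrected Chao1 fallback at zero coverage."""
    s_obs = s_obs.astype(float)
    s_abund = s_obs - s_rare
    with np.errstate(divide="ignore", invalid="ignore"):
        coverage = 1.0 - f1 / n_rare
        gamma2 = np.maximum(
            (s_rare / coverage) * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
        )
        est = s_abund + s_rare / coverage + (f1 / coverage) * gamma2
    no_rare = s_rare == 0
    bad = (~np.isfinite(est)) | (coverage <= 0) | (n_rare < 2)
    est = np.where(no_rare, s_obs, est)
    fallback = bad & ~no_rare
    est = np.where(fallback, _chao1_vec(s_obs, n, f1, f2), est)
    return est, int(fallback.sum())


def _evaluate_assemblage(
    params: SADParams, n: int, config: ScenarioConfig, rng: np.random.Generator
) -> list[dict]:
    """All configured estimators on one assemblage; one result dict each."""
    asm = catch_probabilities(params, config.quantile_convention)
    S = params.S
    n_draws = config.n_draws

    # repeated samples: inverse-CDF lookup of uniforms, tabulated per draw
    u = rng.random((n_draws, n))
    ranks = np.searchsorted(asm.cumprobs, u, side="right")
    cnt_mat = np.empty((n_draws, S), dtype=np.int64)
    for d in range(n_draws):
        cnt_mat[d] = np.bincount(ranks[d], minlength=S)
    del u, ranks

    s_obs, f1, f2, s_rare, n_rare, sum_kk1 = _abundance_stats(cnt_mat)
    meta = dict(
        family=params.family, S=S, N=params.N, cv=params.cv, n=n,
        s_mean=float(s_obs.mean()),
    )

    rows: list[dict] = []

    def add(record: PerformanceRecord, k: int) -> None:
        row = asdict(record)
        row["k"] = k
        rows.append(row)

    wanted_a = [e for e in config.estimators if e in _ABUNDANCE_IDS]
    wanted_i = [e for e in config.estimators if e in _INCIDENCE_IDS]

    for est_id in wanted_a:
        if est_id == "chao1_bc":
            ests, fb = _chao1_vec(s_obs, n, f1, f2), 0
        elif est_id == "jk1a":
            ests, fb = _jk1_vec(s_obs, n, f1), 0
        elif est_id == "jk2a":
            ests, fb = _jk2_vec(s_obs, n, f1, f2), 0
        else:
            ests, fb = _ace_vec(s_obs, n, f1, f2, s_rare, n_rare, sum_kk1)
        rec = mse_abundance(ests, S, estimator_id=est_id, fallback_count=fb, **meta)
        add(rec, 0)

    for k in config.k_splits:
        if not wanted_i or n < k:
            continue
        aggs = {e: np.empty(n_draws) for e in wanted_i}
        svars = {e: np.empty(n_draws) for e in wanted_i}
        fbs = {e: 0 for e in wanted_i}
        for d in range(n_draws):
            if k == 2:
                so, q1, q2 = _split_stats_k2(cnt_mat[d], config.n_splits, rng)
            else:
                so = np.empty(config.n_splits, dtype=np.int64)
                q1 = np.empty(config.n_splits, dtype=np.int64)
                q2 = np.empty(config.n_splits, dtype=np.int64)
                for j in range(config.n_splits):
                    groups = _split_counts(cnt_mat[d], k, rng)
                    inc = (groups > 0).sum(axis=0)
                    so[j] = (inc > 0).sum()
                    q1[j] = (inc == 1).sum()
                    q2[j] = (inc == 2).sum()
            for est_id in wanted_i:
                if k == 2:
                    ests, fb = _estimates_from_q(est_id, so, q1, q2)
                else:
                    ests, fb = _incidence_from_q_general(est_id, k, so, q1, q2)
                ests = np.asarray(ests, dtype=float)
                aggs[est_id][d] = (
                    ests.mean() if config.aggregate == "mean" else np.median(ests)
                )
                svars[est_id][d] = ests.var() if config.n_splits > 1 else 0.0
                fbs[est_id] += fb
        for est_id in wanted_i:
            rec = mse_split(
                aggs[est_id], svars[est_id], S,
                estimator_id=est_id, n_splits=config.n_splits,
                fallback_count=fbs[est_id], **meta,
            )
            add(rec, k)
    return rows


def _incidence_from_q_general(est_id, m, s_obs, q1, q2):
    """Incidence estimates from (s_obs, q1, q2) at arbitrary m.

    Valid for the Chao2 and jackknife forms, whose corrections depend only on
    q1 and q2.  ICE at m in {3, 4} additionally needs q_3, q_4; the sweep
    restricts ICE to 2-way splits where (q1, q2) is the full spectrum.
    """
    from .estimators import _chao2_vec as c2, _jk1_vec as j1, _jk2_vec as j2

    if est_id == "chao2_bc":
        return c2(s_obs, m, q1, q2), 0
    if est_id == "jk1i":
        return j1(s_obs, m, q1), 0
    if est_id == "jk2i":
        return j2(s_obs, m, q1, q2), 0
    raise ValueError(f"ICE supports 2-way splits only (got {m}-way)")


def run_sweep(
    config: ScenarioConfig,
    checkpoint_path: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a sweep; one row per (assemblage, estimator, split arity).

    With ``checkpoint_path`` the table is appended per assemblage and an
    interrupted sweep resumes where it stopped (completed assemblage indices
    are skipped on re-run).
    """
    cells = [
        (family, cv)
        for family in config.sad_families
        for cv in config.cv_grid
    ]
    total = len(cells) * config.n_assemblages
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(total)

    done: set[int] = set()
    old: pd.DataFrame | None = None
    if checkpoint_path is not None and os.path.exists(checkpoint_path):
        old = pd.read_csv(checkpoint_path)
        done = set(old["asm_index"].astype(int))

    all_rows: list[dict] = []
    idx = 0
    for family, cv in cells:
        for _ in range(config.n_assemblages):
            if idx in done:
                idx += 1
                continue
            rng = np.random.default_rng(children[idx])
            params, n = draw_scenario_assemblage(config, cv, rng, family)
            rows = _evaluate_assemblage(params, n, config, rng)
            for row in rows:
                row["asm_index"] = idx
            all_rows.extend(rows)
            if checkpoint_path is not None:
                block = pd.DataFrame(rows)
                block = block.rename(columns={"fallback_count": "fallbacks", "estimator_id": "estimator"})
                block = block[RESULT_COLUMNS]
                block.to_csv(
                    checkpoint_path,
                    mode="a",
                    header=not os.path.exists(checkpoint_path),
                    index=False,
                )
            idx += 1
            if progress and idx % 200 == 0:
                print(f"  assemblage {idx}/{total}", flush=True)

    df = pd.DataFrame(all_rows)
    if not df.empty:
        df = df.rename(columns={"fallback_count": "fallbacks", "estimator_id": "estimator"})
        df = df[RESULT_COLUMNS]
    if old is not None and not old.empty:
        df = pd.concat([old, df], ignore_index=True) if not df.empty else old
    return df.sort_values("asm_index", kind="stable").reset_index(drop=True)


def design_sample_fractions(
    n_pairs: int,
    N_range: Sequence[float] = (1e3, 1e5),
    n_range: Sequence[float] = (300, 5000),
    seed=None,
) -> np.ndarray:
    """Sample fractions n/N (in %) implied by the main sweep's draw design.

    Draws N uniformly, n uniformly with rejection until n < N, and returns
    ``100 * n / N`` for each pair.
    """
    rng = as_rng(seed)
    N = rng.uniform(N_range[0], N_range[1], size=n_pairs)
    n = rng.uniform(n_range[0], n_range[1], size=n_pairs)
    bad = n >= N
    while bad.any():
        n[bad] = rng.uniform(n_range[0], n_range[1], size=int(bad.sum()))
        bad = n >= N
    return 100.0 * n / N
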