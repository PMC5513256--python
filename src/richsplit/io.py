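"""Readers, writers, scenario-config parsing, run manifests and test fixtures.

All on-disk formats are plain text: abundance tables and incidence matrices
as TSV/CSV, scenario configs as flat ``key = value`` files, manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .estimators import IncidenceSet
from .experiments import ScenarioConfig
from .sad import Assemblage, SADParams, catch_probabilities
from .sampling import AbundanceSample, draw_sample

__all__ = [
    "DataError",
    "read_abundance_table",
    "write_abundance_table",
    "read_incidence_matrix",
    "write_incidence_matrix",
    "read_scenario_config",
    "write_scenario_config",
    "RunManifest",
    "fixture_assemblages",
]


class DataError(ValueError):
    """Malformed input data file."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_abundance_table(path) -> AbundanceSample:
    """Read a species x count table (TSV or CSV, columns species_id, count).

    Duplicate species rows are summed with a warning; non-positive or
    non-integer counts raise :class:`DataError` with the offending line.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except Exception as err:
        raise DataError(f"cannot parse {path}: {err}") from err
    required = {"species_id", "count"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns species_id and count, got {list(df.columns)}")
    if df.empty:
        raise DataError(f"{path}: no data rows")
    counts: dict[str, int] = {}
    dupes = set()
    for row_idx, (sp, raw) in enumerate(zip(df["species_id"], df["count"]), start=2):
        try:
            value = int(raw)
        except (TypeError, ValueError):
            raise DataError(f"{path}, line {row_idx}: count {raw!r} is not an integer") from None
        if value <= 0:
            raise DataError(f"{path}, line {row_idx}: count must be positive, got {value}")
        if sp in counts:
            dupes.add(sp)
        counts[sp] = counts.get(sp, 0) + value
    if dupes:
        warnings.warn(
            f"{path}: duplicate species rows summed: {sorted(dupes)}", UserWarning, stacklevel=2
        )
    return AbundanceSample(counts)


def write_abundance_table(sample: AbundanceSample, path) -> None:
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"species_id{sep}count\n")
        for sp, c in sample.counts.items():
            fh.write(f"{sp}{sep}{c}\n")


def read_incidence_matrix(path) -> IncidenceSet:
    """Read a species x sub-sample presence/absence matrix (first column = species).

    Cells must be 0 or 1; species absent from every sub-sample are dropped
    with a warning; fewer than two sub-sample columns is an error.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as err:
        raise DataError(f"cannot parse {path}: {err}") from err
    if df.shape[1] < 2:
        raise DataError(f"{path}: incidence data needs >= 2 sub-sample columns, got {df.shape[1]}")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = df.index[(~np.isin(values, (0, 1))).any(axis=1)][0]
        raise DataError(f"{path}: cells must be 0/1 (species {bad!r} has other values)")
    row_sums = values.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        warnings.warn(
            f"{path}: dropping {int(zero.sum())} all-zero species rows (not observed)",
            UserWarning,
            stacklevel=2,
        )
    incidence = {
        str(sp): int(q) for sp, q in zip(df.index, row_sums) if q > 0
    }
    return IncidenceSet(int(df.shape[1]), incidence)


def write_incidence_matrix(inc: IncidenceSet, path) -> None:
    """Write incidence as a matrix with the first q_i sub-samples marked present.

    The per-sub-sample layout of an :class:`IncidenceSet` is not unique (only
    row sums are stored); this canonical layout round-trips losslessly.
    """
    sep = _sep_for(path)
    cols = [f"subsample_{j + 1}" for j in range(inc.m)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species_id" + sep + sep.join(cols) + "\n")
        for sp, q in inc.incidence.items():
            cells = ["1"] * q + ["0"] * (inc.m - q)
            fh.write(f"{sp}{sep}" + sep.join(cells) + "\n")


# ---------------------------------------------------------------------------
# scenario configs: flat "key = value" text files

_LIST_KEYS = {"sad_families", "cv_grid", "k_splits", "estimators"}
_PAIR_KEYS = {"N_range"}
_INT_KEYS = {"n_assemblages", "n_draws", "n_splits", "seed"}


def read_scenario_config(path) -> ScenarioConfig:
    kv: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataError(f"{path}, line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()

    kwargs: dict = {}
    for key, val in kv.items():
        if key in _LIST_KEYS:
            items = [x.strip() for x in val.split(",") if x.strip()]
            if key in ("cv_grid",):
                kwargs[key] = tuple(float(x) for x in items)
            elif key == "k_splits":
                kwargs[key] = tuple(int(x) for x in items)
            else:
                kwargs[key] = tuple(items)
        elif key in _PAIR_KEYS:
            lo, hi = (float(x) for x in val.split(","))
            kwargs[key] = (lo, hi)
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        elif key in ("S_rule", "n_rule"):
            parts = [x.strip() for x in val.split(",")]
            kwargs[key] = (parts[0], (float(parts[1]), float(parts[2])))
        elif key in ("aggregate", "quantile_convention"):
            kwargs[key] = val
        else:
            raise DataError(f"{path}: unknown scenario key {key!r}")
    try:
        return ScenarioConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise DataError(f"{path}: invalid scenario config: {err}") from err


def write_scenario_config(config: ScenarioConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in dataclasses.fields(config):
            val = getattr(config, f.name)
            if f.name in _LIST_KEYS:
                fh.write(f"{f.name} = {','.join(str(x) for x in val)}\n")
            elif f.name in ("S_rule", "n_rule"):
                kind, (lo, hi) = val
                fh.write(f"{f.name} = {kind},{lo},{hi}\n")
            elif f.name in _PAIR_KEYS:
                fh.write(f"{f.name} = {val[0]},{val[1]}\n")
            else:
                fh.write(f"{f.name} = {val}\n")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every simulation output."""

    command: str
    config_path: str
    seed: int
    version: str
    started: str
    output_paths: tuple

    @classmethod
    def create(cls, command: str, config_path: str, seed: int, outputs) -> "RunManifest":
        return cls(
            command=command,
            config_path=str(config_path),
            seed=int(seed),
            version=__version__,
            started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            output_paths=tuple(str(p) for p in outputs),
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def fixture_assemblages(seed: int = 0, sample_size: int = 100):
    """Deterministic small assemblages + samples for tests and examples.

    Lognormal assemblages on the grid cv in {0.15, 0.65, 0.95} x
    S in {5, 20, 60} with mean abundance 1000, each paired with one sample of
    ``sample_size`` individuals.  Keyed by (cv, S).
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[float, int], tuple[Assemblage, AbundanceSample]] = {}
    for cv in (0.15, 0.65, 0.95):
        for S in (5, 20, 60):
            params = SADParams.create("lognormal", S, 1000.0, cv)
            asm = catch_probabilities(params)
            sample = draw_sample(asm, sample_size, rng)
            out[(cv, S)] = (asm, sample)
    return out
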