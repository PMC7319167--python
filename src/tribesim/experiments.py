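"""Scenario presets, replicate execution, and output writing.

The preset catalog covers the study scenarios: three culture types
(Machiavellian = selfish TrE memes, cooperative = group-beneficial HE
memes, complex = both) crossed with three levels of between-group
competition (maximum group size 800 = a single undivided group, 40 =
moderate, 15 = strong), each also in a costly-evolvable-learning
variant; a five-category run in which learning and teaching evolve both
genetically and culturally; and single-factor variants (population x3,
creativity x3, life span x2, migration 0 and x4) of the complex
costly-learning G=40 scenario.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .config import ConfigError, WorldConfig, read_config, write_config
from .genetics import LocusSpec
from .memes import CATEGORIES, MemeCategoryParams
from .population import run_simulation
from .stats import STAT_COLUMNS

#: Figure-style summary window (years); configurable per call for
#: scaled-down runs.
DEFAULT_WINDOW: tuple[int, int] = (50_000, 70_000)

#: Replicate count used by the study's figures.
DEFAULT_REPLICATES = 10

#: Default run length of the full-scale scenarios (years).
DEFAULT_YEARS = 70_000


@dataclass(frozen=True)
class ExperimentPreset:
    """A named, fully resolved scenario."""

    name: str
    config: WorldConfig
    years: int = DEFAULT_YEARS
    replicates: int = DEFAULT_REPLICATES
    description: str = ""


def _enable(config: WorldConfig, categories: Sequence[str],
            invention_rate: Optional[float] = None) -> WorldConfig:
    """Enable exactly the given meme categories (others disabled)."""
    params = {}
    for cat, p in config.meme_params.items():
        rate = p.invention_rate if invention_rate is None else invention_rate
        params[cat] = dataclasses.replace(
            p, enabled=(cat in categories), invention_rate=rate)
    return config.replace(meme_params=params)


def _costly_le(config: WorldConfig) -> WorldConfig:
    """Costly, evolvable learning efficiency: LE starts at 0, mutates
    (rate 0.04, sd 0.1), and each unit of genotypic LE costs 30 units of
    brain volume."""
    loci = dict(config.locus_specs)
    loci["LE"] = LocusSpec("LE", initial_value=0.0, mutation_rate=0.04,
                           mutation_sd=0.1, lower_bound=0.0, upper_bound=1.0)
    return config.replace(locus_specs=loci, k2=30.0)


def _five_category(config: WorldConfig) -> WorldConfig:
    """All five meme categories; LE and TE evolve genetically (rate 0.04,
    sd 0.1; initial LE 0.05, TE 0) and culturally; brain volume =
    20 + MC + 30*(LE_g + TE_g)."""
    loci = dict(config.locus_specs)
    loci["LE"] = LocusSpec("LE", initial_value=0.05, mutation_rate=0.04,
                           mutation_sd=0.1, lower_bound=0.0, upper_bound=1.0)
    loci["TE"] = LocusSpec("TE", initial_value=0.0, mutation_rate=0.04,
                           mutation_sd=0.1, lower_bound=0.0, upper_bound=1.0)
    config = config.replace(locus_specs=loci, k2=30.0, k3=30.0)
    return _enable(config, CATEGORIES)


_CULTURES: dict[str, tuple[str, ...]] = {
    "machiavellian": ("TrE", "Useless"),
    "cooperative": ("HE", "Useless"),
    "complex": ("TrE", "HE", "Useless"),
}


def preset_catalog() -> dict[str, ExperimentPreset]:
    """Build the full named-scenario catalog."""
    catalog: dict[str, ExperimentPreset] = {}

    def add(name: str, config: WorldConfig, description: str,
            years: int = DEFAULT_YEARS) -> None:
        catalog[name] = ExperimentPreset(name, config, years=years,
                                         replicates=DEFAULT_REPLICATES,
                                         description=description)

    for culture, cats in _CULTURES.items():
        for g in (800, 40, 15):
            base = _enable(WorldConfig(G_max=g), cats)
            add(f"{culture}_G{g}", base,
                f"{culture} culture ({'+'.join(cats)} memes), max group size {g}")
            add(f"{culture}_costlyLE_G{g}", _costly_le(base),
                f"{culture} culture, max group size {g}, costly evolvable LE")

    add("five_category_G40", _five_category(WorldConfig(G_max=40)),
        "all five meme categories, LE/TE evolve genetically and culturally, "
        "max group size 40")

    basic = catalog["complex_costlyLE_G40"].config
    add("complex_costlyLE_G40_population_x3", basic.replace(R_env=9000.0),
        "complex costly-LE G40 with tripled environment supply (R=9,000)")
    add("complex_costlyLE_G40_creativity_x3", _enable(
        basic, _CULTURES["complex"], invention_rate=0.0004),
        "complex costly-LE G40 with tripled invention rate (0.0004 per category)")
    add("complex_costlyLE_G40_lifespan_x2", basic.replace(death_coeff=0.0005),
        "complex costly-LE G40 with halved death hazard (age x 0.0005)")
    add("complex_costlyLE_G40_migration_0", basic.replace(migration_rate=0.0),
        "complex costly-LE G40 with no between-group migration")
    add("complex_costlyLE_G40_migration_x4", basic.replace(migration_rate=0.004),
        "complex costly-LE G40 with quadrupled migration (0.004 per year)")
    return catalog


def get_preset(name: str) -> ExperimentPreset:
    catalog = preset_catalog()
    if name not in catalog:
        known = ", ".join(sorted(catalog))
        raise KeyError(f"unknown preset {name!r}; available presets: {known}")
    return catalog[name]


# ----------------------------------------------------------------------
# replicates


@dataclass
class ReplicateResult:
    """Aggregated outcome of several independent runs of one scenario."""

    per_run: list[pd.DataFrame]
    seeds: list[int]
    per_year_mean: pd.DataFrame
    window_mean: pd.Series
    window: tuple[int, int]
    extinctions: list[int] = field(default_factory=list)


def run_replicates(config: WorldConfig, n_runs: int, base_seed: int,
                   years: Optional[int] = None,
                   window: Optional[tuple[int, int]] = None,
                   progress: bool = False) -> ReplicateResult:
    """Run ``n_runs`` independent simulations with seeds ``base_seed ..
    base_seed + n_runs - 1`` and aggregate per-year cross-run means plus a
    windowed mean over a year range (default years 50,000-70,000).

    Replicates that go extinct are kept in the aggregates for the years
    they lived and recorded in ``extinctions``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if years is None:
        years = config.years
    lo, hi = window if window is not None else DEFAULT_WINDOW
    runs: list[pd.DataFrame] = []
    seeds: list[int] = []
    extinctions: list[int] = []
    for r in range(n_runs):
        seed = base_seed + r
        cfg = config.replace(seed=seed, years=years)
        df = run_simulation(cfg, progress=progress)
        runs.append(df)
        seeds.append(seed)
        if not df.empty and bool(df["extinct"].iloc[-1]):
            extinctions.append(seed)
    pooled = pd.concat(runs, ignore_index=True)
    per_year = pooled.groupby("year", as_index=False).mean(numeric_only=True)
    in_window = per_year[(per_year["year"] >= lo) & (per_year["year"] <= hi)]
    if in_window.empty:  # window beyond the run length: fall back to all years
        in_window = per_year
    window_mean = in_window.drop(columns=["year"]).mean()
    return ReplicateResult(per_run=runs, seeds=seeds, per_year_mean=per_year,
                           window_mean=window_mean, window=(lo, hi),
                           extinctions=extinctions)


# ----------------------------------------------------------------------
# outputs


def write_outputs(trajectory: pd.DataFrame, out_dir, config: WorldConfig,
                  seeds: Sequence[int] = (), runtime_s: Optional[float] = None,
                  name: str = "run") -> tuple[Path, Path]:
    """Write a per-year CSV plus a JSON metadata file (resolved config,
    seeds, runtime, package version).  Returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{name}.csv"
    meta_path = out / f"{name}.meta.json"
    trajectory.to_csv(csv_path, index=False)
    meta = {
        "name": name,
        "version": __version__,
        "config": _jsonable(config.to_dict()),
        "seeds": list(seeds),
        "runtime_s": runtime_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "columns": list(trajectory.columns),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return csv_path, meta_path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return ".inf"
    return obj
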