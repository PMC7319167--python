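"""World configuration: every tunable parameter of a simulation run.

Defaults follow the baseline scenario: a resource-limited environment
producing ``R_env`` resources per year, yearly costs for life support,
hunting and useless actions, an age-proportional death hazard, costly
reproduction scaled by the child's brain volume, and a single mutable
memory-capacity locus.  Scenario presets override pieces of this
(see :mod:`tribesim.experiments`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import math

import yaml

from .genetics import LOCUS_ORDER, LocusSpec
from .memes import CATEGORIES, MemeCategoryParams


class ConfigError(ValueError):
    """Invalid or incomplete world configuration; names the offending key."""


def default_locus_specs() -> dict[str, LocusSpec]:
    """MC evolvable (rate 0.04, sd 0.4, bounded below at 0); LE fixed at 1
    (perfect congenital copying); TE fixed at 0."""
    return {
        "MC": LocusSpec("MC", initial_value=0.0, mutation_rate=0.04,
                        mutation_sd=0.4, lower_bound=0.0, upper_bound=math.inf),
        "LE": LocusSpec("LE", initial_value=1.0, mutation_rate=0.0,
                        mutation_sd=0.0, lower_bound=0.0, upper_bound=1.0),
        "TE": LocusSpec("TE", initial_value=0.0, mutation_rate=0.0,
                        mutation_sd=0.0, lower_bound=0.0, upper_bound=1.0),
    }


def default_meme_params() -> dict[str, MemeCategoryParams]:
    """Category defaults: additive-trait memes (TrE, HE) have mean
    efficiency 4, sd 6, size coefficient 0.25, noise spread 2 (mean size 1);
    probability-valued memes (Useless, LE, TE) have mean efficiency 0.2,
    sd 0.3, size coefficient 5, noise spread 2.  Only TrE and Useless are
    enabled by default (Machiavellian culture)."""
    return {
        "TrE": MemeCategoryParams("TrE", 4.0, 6.0, 0.25, 2.0, enabled=True),
        "HE": MemeCategoryParams("HE", 4.0, 6.0, 0.25, 2.0, enabled=False),
        "Useless": MemeCategoryParams("Useless", 0.2, 0.3, 5.0, 2.0, enabled=True),
        "LE": MemeCategoryParams("LE", 0.2, 0.3, 5.0, 2.0, enabled=False),
        "TE": MemeCategoryParams("TE", 0.2, 0.3, 5.0, 2.0, enabled=False),
    }


@dataclass
class WorldConfig:
    """Full parameter set of one simulation run."""

    # environment and group structure
    R_env: float = 3000.0
    G_max: int = 800

    # yearly action costs
    life_support_cost: float = 3.0
    hunt_cost: float = 2.0
    useless_cost: float = 1.0

    # rates
    p_forget: float = 0.02
    migration_rate: float = 0.001
    death_coeff: float = 0.002

    # reproduction
    min_repro_age: int = 6          # eligibility is strictly age > this
    child_cost_multiplier: float = 2.0
    transfer_fraction: float = 0.4

    # brain-volume cost coefficients: base + k1*MC + k2*LE_g + k3*TE_g
    brain_base: float = 20.0
    k1: float = 1.0
    k2: float = 0.0
    k3: float = 0.0

    # fixed genetic bases (non-mutating)
    he_base: float = 10.0
    tre_base: float = 0.0

    # loci and meme categories
    locus_specs: dict[str, LocusSpec] = field(default_factory=default_locus_specs)
    meme_params: dict[str, MemeCategoryParams] = field(default_factory=default_meme_params)

    # run control
    years: int = 2000
    seed: int = 0

    # initial population
    initial_population: int = 250
    initial_resources: float = 10.0
    initial_max_age: int = 20

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------

    def validate(self) -> None:
        for key in ("p_forget", "migration_rate", "transfer_fraction"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}: expected a rate in [0, 1], got {v}")
        for key in ("R_env", "life_support_cost", "hunt_cost", "useless_cost",
                    "death_coeff", "child_cost_multiplier", "brain_base",
                    "he_base", "tre_base"):
            v = getattr(self, key)
            if v < 0:
                raise ConfigError(f"{key}: expected >= 0, got {v}")
        if self.G_max < 2:
            raise ConfigError(f"G_max: expected >= 2, got {self.G_max}")
        if self.initial_population < 2:
            raise ConfigError(
                f"initial_population: expected >= 2, got {self.initial_population}")
        if self.years < 0:
            raise ConfigError(f"years: expected >= 0, got {self.years}")
        for name in LOCUS_ORDER:
            if name not in self.locus_specs:
                raise ConfigError(f"locus_specs: missing required locus {name!r}")
        for name, spec in self.locus_specs.items():
            if spec.name != name:
                raise ConfigError(f"locus_specs[{name!r}]: spec is for {spec.name!r}")
        for cat, params in self.meme_params.items():
            if params.category != cat:
                raise ConfigError(
                    f"meme_params[{cat!r}]: parameters are for {params.category!r}")

    # -- convenience -------------------------------------------------

    @property
    def ordered_locus_specs(self) -> tuple[LocusSpec, ...]:
        return tuple(self.locus_specs[name] for name in LOCUS_ORDER)

    @property
    def enabled_meme_params(self) -> tuple[MemeCategoryParams, ...]:
        return tuple(p for c, p in self.meme_params.items() if p.enabled)

    def replace(self, **changes: Any) -> "WorldConfig":
        """Copy with field overrides (nested dicts are shallow-copied)."""
        base = dataclasses.replace(self)
        base.locus_specs = dict(self.locus_specs)
        base.meme_params = dict(self.meme_params)
        for key, value in changes.items():
            if not hasattr(base, key):
                raise ConfigError(f"unknown configuration key {key!r}")
            setattr(base, key, value)
        base.validate()
        return base

    # -- serialization -----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
             if f.name not in ("locus_specs", "meme_params")}
        d["locus_specs"] = {
            name: _spec_dict(spec) for name, spec in self.locus_specs.items()}
        d["meme_params"] = {
            cat: dataclasses.asdict(p) for cat, p in self.meme_params.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "WorldConfig":
        data = dict(data)
        loci = data.pop("locus_specs", None)
        memes = data.pop("meme_params", None)
        field_names = {f.name for f in dataclasses.fields(cls)}
        for key in data:
            if key not in field_names:
                raise ConfigError(f"unknown configuration key {key!r}")
        kwargs: dict[str, Any] = dict(data)
        if loci is not None:
            specs = {}
            for name, spec in loci.items():
                try:
                    specs[name] = (
                        spec if isinstance(spec, LocusSpec)
                        else LocusSpec(**_undump_inf(spec)))
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"locus_specs[{name!r}]: {exc}") from exc
            kwargs["locus_specs"] = specs
        if memes is not None:
            params = {}
            for cat, p in memes.items():
                try:
                    params[cat] = (
                        p if isinstance(p, MemeCategoryParams)
                        else MemeCategoryParams(**p))
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"meme_params[{cat!r}]: {exc}") from exc
            kwargs["meme_params"] = params
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _spec_dict(spec: LocusSpec) -> dict[str, Any]:
    d = dataclasses.asdict(spec)
    if d["upper_bound"] == math.inf:
        d["upper_bound"] = ".inf"
    return d


def _undump_inf(d: Mapping[str, Any]) -> dict[str, Any]:
    d = dict(d)
    if d.get("upper_bound") in (".inf", "inf", None):
        d["upper_bound"] = math.inf
    return d


def read_config(path) -> WorldConfig:
    """Read a YAML configuration file into a validated :class:`WorldConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return WorldConfig.from_dict(data)


def write_config(config: WorldConfig, path) -> None:
    """Write a configuration as YAML; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
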