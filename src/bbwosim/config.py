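"""Configuration schema, defaults, and YAML round-trip.

An empty configuration file yields a fully defaulted setup: the shipped
species trait table, the five-type habitat coefficient table, a three-region
fire zonation, and climate-trend multipliers that encode only sign and
ordering (conifers decline with forcing, warm-adapted deciduous species
gain).  Unknown keys and out-of-range values are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import yaml

from .core import (
    DEFAULT_HABITAT_COEFFS,
    DEFAULT_TRAITS,
    GridSpec,
    HabitatCoefficients,
    HabitatType,
    PostFireRegen,
    SpeciesTraits,
)

__all__ = [
    "Config",
    "SyntheticConfig",
    "FireConfig",
    "SBWConfig",
    "HarvestConfig",
    "HabitatConfig",
    "SuccessionConfig",
    "ClimateTrendConfig",
    "read_config",
    "write_config",
    "ConfigError",
]

SCENARIOS = ("baseline", "rcp26", "rcp45", "rcp85")
#: Climate periods between which climate-sensitive parameters switch.
PERIODS = ("2000-2010", "2011-2040", "2041-2070", "2071-2100")
#: Progress of each period along the century (drives trend interpolation).
PERIOD_PHASE = {"2000-2010": 0.0, "2011-2040": 1 / 3, "2041-2070": 2 / 3, "2071-2100": 1.0}
#: Relative forcing strength of each pathway (orders the scenarios).
FORCING = {"baseline": 0.0, "rcp26": 0.3, "rcp45": 0.6, "rcp85": 1.0}

#: Default species pool for synthetic landscapes: the dominant boreal
#: conifers plus the main pioneer deciduous species, with relative abundances.
DEFAULT_SPECIES_POOL = {
    "PICE.MAR": 0.35,
    "ABIE.BAL": 0.20,
    "PINU.BAN": 0.10,
    "PICE.GLA": 0.05,
    "LARI.LAR": 0.03,
    "POPU.TRE": 0.12,
    "BETU.PAP": 0.10,
    "ACER.RUB": 0.05,
}


class ConfigError(ValueError):
    """Invalid configuration file contents."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape generator."""

    n_fire_regions: int = 3
    n_management_areas: int = 5
    private_fraction: float = 0.127
    conifer_gradient: tuple[float, float] = (0.4, 0.95)  # (south, north)
    age_distribution_mean: float = 150.0  # yr, fire-cycle surrogate
    species_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_POOL)
    )
    n_landtypes: int = 5
    initial_stocking: float = 0.75  # initial biomass as fraction of asymptote
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.private_fraction <= 1):
            raise ConfigError("private_fraction must be in [0, 1]")
        if any(not 0 <= g <= 1 for g in self.conifer_gradient):
            raise ConfigError("conifer_gradient endpoints must be in [0, 1]")
        if self.age_distribution_mean <= 0:
            raise ConfigError("age_distribution_mean must be positive")
        if not self.species_pool:
            raise ConfigError("species_pool must not be empty")
        for code in self.species_pool:
            if code not in DEFAULT_TRAITS:
                raise ConfigError(f"unknown species in pool: {code}")
        if self.n_fire_regions < 1 or self.n_management_areas < 1:
            raise ConfigError("need at least one fire region and management area")


@dataclass
class FireConfig:
    """Baseline fire regime and its climate sensitivity.

    ``annual_burn_rate`` is the expected fraction of a fire region burned per
    year under the baseline climate (per-region values override the scalar).
    Climate change scales the burn rate linearly up to ``rate_multiplier_max``
    at full forcing by the end of the century.
    """

    annual_burn_rate: float = 1.0 / 150.0
    region_burn_rates: dict[int, float] | None = None
    mean_fire_size: float = 500.0  # hectares
    size_cv: float = 1.0  # CV of the lognormal fire-size distribution
    rate_multiplier_max: float = 5.0
    size_multiplier_max: float = 1.5
    spread_prob: float = 1.0  # neighbour accretion probability during spread

    def validate(self) -> None:
        if self.annual_burn_rate < 0:
            raise ConfigError("annual_burn_rate must be non-negative")
        if self.mean_fire_size <= 0:
            raise ConfigError("mean_fire_size must be positive")
        if self.size_cv < 0:
            raise ConfigError("size_cv must be non-negative")
        if not 0 < self.spread_prob <= 1:
            raise ConfigError("spread_prob must be in (0, 1]")


@dataclass
class SBWParams:
    """Spruce budworm outbreak regime and host impacts.

    Outbreaks recur every ``recurrence`` years (first one at ``phase``) and
    last at most ``max_duration`` years.  ``host_ranking`` orders hosts from
    most to least vulnerable; ``rank_severity`` scales the age-dependent
    mortality fractions ``age_mortality`` (applied to cohorts <30, 30-60 and
    >60 yr old) down the ranking.
    """

    recurrence: int = 35
    max_duration: int = 10
    phase: int = 35  # simulation year of the first outbreak onset
    host_ranking: tuple[str, ...] = ("ABIE.BAL", "PICE.GLA", "PICE.RUB", "PICE.MAR")
    rank_severity: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    age_mortality: tuple[float, float, float] = (0.25, 0.55, 0.85)

    def validate(self) -> None:
        if self.recurrence <= self.max_duration:
            raise ConfigError("recurrence must exceed max_duration")
        if len(self.rank_severity) != len(self.host_ranking):
            raise ConfigError("rank_severity must match host_ranking length")
        for f in list(self.age_mortality) + list(self.rank_severity):
            if not 0 <= f <= 1:
                raise ConfigError("mortality fractions must be in [0, 1]")


@dataclass
class HarvestConfig:
    """Harvest scheduling: a constant area target per management area.

    ``annual_rate`` is the fraction of each management area scheduled per
    year (regional rates run about 0.4-0.8%/yr).  Public-land management
    areas are clearcut; private-land areas alternate between the two
    partial-harvest classes.
    """

    annual_rate: float = 0.006
    eligibility_age: int = 60
    partial_low: tuple[float, float] = (0.01, 0.40)
    partial_high: tuple[float, float] = (0.41, 0.80)
    patch_clustered: bool = False

    def validate(self) -> None:
        if self.annual_rate < 0:
            raise ConfigError("annual_rate must be non-negative")
        for lo, hi in (self.partial_low, self.partial_high):
            if not 0 <= lo <= hi <= 1:
                raise ConfigError("partial-harvest bounds must satisfy 0<=lo<=hi<=1")


@dataclass
class HabitatConfig:
    """Habitat classification thresholds and patch-analysis options."""

    conif_threshold: float = 0.75
    mixed_lower: float = 0.25
    connectivity: int = 4
    count_mode: str = "patches"  # or "home_ranges"
    coefficients: HabitatCoefficients = field(default=DEFAULT_HABITAT_COEFFS)

    def validate(self) -> None:
        if not 0 <= self.mixed_lower < self.conif_threshold <= 1:
            raise ConfigError("need 0 <= mixed_lower < conif_threshold <= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.count_mode not in ("patches", "home_ranges"):
            raise ConfigError("count_mode must be 'patches' or 'home_ranges'")


@dataclass
class SuccessionConfig:
    """Numerical knobs of the cohort succession model."""

    #: Maximum relative occupancy (total biomass / maxAGB) under which a
    #: species of shade tolerance 1..5 can still establish.
    light_thresholds: tuple[float, ...] = (0.25, 0.45, 0.65, 0.85, 1.0)
    #: Fraction of longevity at which senescence mortality becomes
    #: noticeable is governed by each species' mortality_shape (see flm).
    regen_biomass: float = 0.5  # t/ha given to fire-origin regeneration cohorts

    def validate(self) -> None:
        if len(self.light_thresholds) != 5:
            raise ConfigError("light_thresholds needs one value per tolerance class")
        if list(self.light_thresholds) != sorted(self.light_thresholds):
            raise ConfigError("light_thresholds must be non-decreasing")


@dataclass
class ClimateTrendConfig:
    """Sign/ordering structure of climate effects on stand-scale parameters.

    Multipliers interpolate linearly from 1 at the start of the century to
    ``1 - decline`` (or ``1 + gain``) at full forcing in 2071-2100; weaker
    pathways scale by their relative forcing.  These defaults encode only
    the direction and ordering of projected changes, not magnitudes.
    """

    conifer_decline: float = 0.40
    black_spruce_extra_decline: float = 0.15
    deciduous_gain: float = 0.30
    sep_follows_growth: bool = True

    def validate(self) -> None:
        for v in (self.conifer_decline, self.deciduous_gain):
            if v < 0:
                raise ConfigError("trend magnitudes must be non-negative")
        if self.conifer_decline + self.black_spruce_extra_decline > 1:
            raise ConfigError("total conifer decline cannot exceed 100%")


@dataclass
class Config:
    """Top-level configuration for the whole pipeline."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(n_rows=100, n_cols=100))
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fire: FireConfig = field(default_factory=FireConfig)
    sbw: SBWParams = field(default_factory=SBWParams)
    harvest: HarvestConfig = field(default_factory=HarvestConfig)
    habitat: HabitatConfig = field(default_factory=HabitatConfig)
    succession: SuccessionConfig = field(default_factory=SuccessionConfig)
    climate: ClimateTrendConfig = field(default_factory=ClimateTrendConfig)
    species: dict[str, SpeciesTraits] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )

    def validate(self) -> "Config":
        for section in (
            self.synthetic,
            self.fire,
            self.sbw,
            self.harvest,
            self.habitat,
            self.succession,
            self.climate,
        ):
            section.validate()
        for code in self.synthetic.species_pool:
            if code not in self.species:
                raise ConfigError(f"species_pool references unknown species {code}")
        return self


# -- dict <-> dataclass plumbing --------------------------------------------

_TUPLE_FIELDS = {
    "conifer_gradient",
    "host_ranking",
    "rank_severity",
    "age_mortality",
    "partial_low",
    "partial_high",
    "light_thresholds",
}


def _build(cls, data: Mapping[str, Any], where: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _species_from_dict(data: Mapping[str, Any]) -> dict[str, SpeciesTraits]:
    """Species table: defaults overridden/extended per species code."""
    table = dict(DEFAULT_TRAITS)
    for code, override in data.items():
        if not isinstance(override, Mapping):
            raise ConfigError(f"species.{code}: expected a mapping of trait overrides")
        base = dataclasses.asdict(table[code]) if code in table else {"code": code}
        merged = {**base, **override, "code": code}
        merged["post_fire_regen"] = PostFireRegen(merged["post_fire_regen"])
        try:
            table[code] = SpeciesTraits(**merged)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"species.{code}: {exc}") from exc
    return table


def _habitat_from_dict(data: Mapping[str, Any]) -> HabitatConfig:
    data = dict(data)
    coeffs = data.pop("coefficients", None)
    cfg = _build(HabitatConfig, data, "habitat")
    if coeffs is not None:
        try:
            hr = {HabitatType(k): float(v["home_range"]) for k, v in coeffs.items()}
            pr = {HabitatType(k): float(v["productivity"]) for k, v in coeffs.items()}
            cfg.coefficients = HabitatCoefficients(home_range=hr, productivity=pr)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"habitat.coefficients: {exc}") from exc
    return cfg


def config_from_dict(data: Mapping[str, Any] | None) -> Config:
    data = dict(data or {})
    sections = {
        "grid": lambda d: _build(GridSpec, d, "grid"),
        "synthetic": lambda d: _build(SyntheticConfig, d, "synthetic"),
        "fire": lambda d: _build(FireConfig, d, "fire"),
        "sbw": lambda d: _build(SBWParams, d, "sbw"),
        "harvest": lambda d: _build(HarvestConfig, d, "harvest"),
        "habitat": _habitat_from_dict,
        "succession": lambda d: _build(SuccessionConfig, d, "succession"),
        "climate": lambda d: _build(ClimateTrendConfig, d, "climate"),
        "species": _species_from_dict,
    }
    unknown = set(data) - set(sections)
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    kwargs = {name: builder(data[name]) for name, builder in sections.items() if name in data}
    return Config(**kwargs).validate()


def config_to_dict(cfg: Config) -> dict[str, Any]:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, HabitatCoefficients):  # pragma: no cover - handled below
            return obj
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, PostFireRegen):
            return obj.value
        return obj

    out = {
        "grid": plain(cfg.grid),
        "synthetic": plain(cfg.synthetic),
        "fire": plain(cfg.fire),
        "sbw": plain(cfg.sbw),
        "harvest": plain(cfg.harvest),
        "habitat": {
            "conif_threshold": cfg.habitat.conif_threshold,
            "mixed_lower": cfg.habitat.mixed_lower,
            "connectivity": cfg.habitat.connectivity,
            "count_mode": cfg.habitat.count_mode,
            "coefficients": {
                ht.value: {
                    "home_range": cfg.habitat.coefficients.home_range[ht],
                    "productivity": cfg.habitat.coefficients.productivity[ht],
                }
                for ht in cfg.habitat.coefficients.home_range
            },
        },
        "succession": plain(cfg.succession),
        "climate": plain(cfg.climate),
        "species": {
            code: {
                k: (v.value if isinstance(v, PostFireRegen) else v)
                for k, v in dataclasses.asdict(tr).items()
                if k != "code"
            }
            for code, tr in cfg.species.items()
        },
    }
    return out


def read_config(path) -> Config:
    """Read and validate a YAML configuration; an empty file gives defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def write_config(cfg: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
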