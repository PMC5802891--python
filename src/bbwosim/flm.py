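"""Simplified cohort-based forest landscape model.

One 5-yr step applies, in order: climate-period parameter lookup, cohort
succession (aging, senescence, competition-limited growth, dispersal-gated
establishment), stochastic fire, scheduled spruce-budworm outbreaks, and
harvesting.  The succession equations are a stated simplification: a
logistic-style, growing-space-limited biomass increment with species shape
modifiers, chosen to yield realistic age/composition dynamics rather than
bit-compatibility with any particular forest landscape simulator.

Randomness policy: each stochastic process (fire, harvest, establishment,
budworm) draws from its own named stream derived from the master seed, so
toggling one process never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .config import Config, FORCING, PERIODS, PERIOD_PHASE, SBWParams
from .core import GridSpec, LandscapeState, PostFireRegen, SpeciesTraits
from .synthetic import DynamicInputs, generate_dynamic_inputs

__all__ = [
    "FireRegimeParams",
    "HarvestPrescription",
    "Toggles",
    "Snapshot",
    "SimulationResult",
    "sep_from_establishment_time",
    "dispersal_rate",
    "seed_arrival_probability",
    "sample_dispersal_distance",
    "disperse_seeds",
    "step_succession",
    "simulate_fire",
    "apply_sbw",
    "sbw_outbreak_active",
    "apply_harvest",
    "build_fire_regime",
    "build_prescriptions",
    "update_climate_period",
    "run_simulation",
]

_TINY_BIOMASS = 1e-3  # t/ha; cohorts below this are considered dead


# ---------------------------------------------------------------------------
# establishment probability from mean establishment time
# ---------------------------------------------------------------------------

def sep_from_establishment_time(t: float, timestep: int = 5) -> float:
    """Establishment probability per timestep from mean establishment time.

    Annual establishment is a Bernoulli trial with probability ``1/t``; the
    per-timestep probability is that of at least one success in ``timestep``
    consecutive trials: ``1 - (1 - 1/t)**timestep``.
    """
    if t < 1:
        raise ValueError("mean establishment time must be >= 1 yr")
    return 1.0 - (1.0 - 1.0 / t) ** timestep


# ---------------------------------------------------------------------------
# seed dispersal
# ---------------------------------------------------------------------------

def dispersal_rate(traits: SpeciesTraits) -> float:
    """Decay rate of the dispersal kernel (per metre).

    The dispersal distance follows an exponential distribution truncated at
    ``maximum_dispersal``, with the rate chosen so that 95% of dispersal
    falls within ``effective_dispersal``.
    """
    ed, md = traits.effective_dispersal, traits.maximum_dispersal
    if ed == md:
        return np.log(20.0) / ed

    def q95(lam: float) -> float:
        return (1 - np.exp(-lam * ed)) / (1 - np.exp(-lam * md)) - 0.95

    return brentq(q95, 1e-9, 100.0 / ed)


def seed_arrival_probability(traits: SpeciesTraits, distance) -> np.ndarray:
    """Probability that seed from a source reaches at least ``distance`` (m).

    1 at distance 0, 0 beyond ``maximum_dispersal``.
    """
    d = np.asarray(distance, dtype=float)
    lam = dispersal_rate(traits)
    md = traits.maximum_dispersal
    denom = 1.0 - np.exp(-lam * md)
    surv = (np.exp(-lam * np.minimum(d, md)) - np.exp(-lam * md)) / denom
    return np.where(d > md, 0.0, surv)


def sample_dispersal_distance(
    traits: SpeciesTraits, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw dispersal distances (m) from the truncated exponential kernel."""
    lam = dispersal_rate(traits)
    u = rng.random(size)
    cap = 1.0 - np.exp(-lam * traits.maximum_dispersal)
    return -np.log(1.0 - u * cap) / lam


def disperse_seeds(
    state: LandscapeState,
    species: str,
    traits: Mapping[str, SpeciesTraits],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-cell boolean: can ``species`` establish here this step (seed-wise)?

    A cell with a mature cohort of the species is always a source for
    itself; other cells receive seed with a probability set by the distance
    to the nearest mature source through the dispersal kernel.  Vegetative
    regeneration makes any cell already containing the species a local
    source regardless of maturity.
    """
    tr = traits[species]
    s = state.species_index(species)
    ts = state.grid.timestep
    mature_class = -(-tr.maturity_age // ts)  # ceil division
    present = state.biomass[s] > 0  # (age_class, cell)
    mature = present[mature_class:].any(axis=0)
    if tr.vegetative_regen:
        local = present.any(axis=0)
    else:
        local = mature
    if not mature.any():
        return local.copy()
    shape = (state.grid.n_rows, state.grid.n_cols)
    dist = ndimage.distance_transform_edt(
        ~mature.reshape(shape), sampling=state.grid.cell_size_m
    ).ravel()
    p = seed_arrival_probability(tr, dist)
    out = rng.random(state.n_cells) < p
    out |= local
    return out


# ---------------------------------------------------------------------------
# succession
# ---------------------------------------------------------------------------

def _growth_factor(shape: float, age: np.ndarray, longevity: int) -> np.ndarray:
    """Age modifier of the growth increment.

    Shape 0: constant potential over life.  Shape 1: a symmetric ramp
    peaking at half the lifespan (slow juvenile and senescent growth).
    """
    if shape == 0:
        return np.ones_like(age, dtype=float)
    p = np.clip(age / longevity, 0.0, 1.0)
    return np.maximum(4.0 * p * (1.0 - p), 0.1)


def _senescence_fraction(shape: float, age: np.ndarray, longevity: int) -> np.ndarray:
    """Per-step mortality fraction from senescence.

    Exponential onset controlled by the mortality shape: negligible through
    most of the lifespan, reaching 1 (full removal) at ``longevity``.
    """
    m = np.exp(shape * (age.astype(float) - longevity) / longevity)
    return np.where(age >= longevity, 1.0, np.minimum(m, 1.0))


def step_succession(
    state: LandscapeState,
    dyn_tables: Mapping[str, np.ndarray],
    traits: Mapping[str, SpeciesTraits],
    rng: np.random.Generator,
    light_thresholds: Sequence[float] = (0.25, 0.45, 0.65, 0.85, 1.0),
    regen_biomass: float = 0.5,
) -> LandscapeState:
    """Advance cohorts one timestep (in place) and return the state.

    Per cell: (1) ages advance; (2) senescence removes biomass with onset
    shaped by each species' mortality shape, and cohorts at/past longevity
    die; (3) each cohort gains ``timestep * maxANPP * growth-shape-factor *
    (1 - B_tot / maxAGB)`` biomass (floored at 0, kg converted to t), so
    cell biomass never exceeds its carrying capacity; (4) species with a
    seed source and adequate light establish a new cohort with probability
    SEP.  ``dyn_tables`` holds the current period's ``sep``/``maxanpp``/
    ``maxagb`` arrays over (species, landtype).
    """
    ts = state.grid.timestep
    lt = state.landtype
    ages = state.class_ages

    # (1) aging
    state.biomass[:, 1:, :] = state.biomass[:, :-1, :]
    state.biomass[:, 0, :] = 0.0

    # (2) senescence / longevity
    for s, code in enumerate(state.species):
        tr = traits[code]
        surv = 1.0 - _senescence_fraction(tr.mortality_shape, ages, tr.longevity)
        state.biomass[s] *= surv[:, None]

    state.biomass[state.biomass < _TINY_BIOMASS] = 0.0

    # (3) growth, limited by growing space
    total = state.biomass.sum(axis=(0, 1))
    n_sp = len(state.species)
    maxagb_cell = dyn_tables["maxagb"][:, lt]  # (species, cell)
    increments = np.zeros_like(state.biomass)
    for s, code in enumerate(state.species):
        tr = traits[code]
        present = state.biomass[s] > 0
        if not present.any():
            continue
        gf = _growth_factor(tr.growth_shape, ages, tr.longevity)
        space = np.maximum(1.0 - total / np.maximum(maxagb_cell[s], 1e-9), 0.0)
        inc = (ts * dyn_tables["maxanpp"][s, lt] / 1000.0) * space
        increments[s] = present * gf[:, None] * inc[None, :]
    # never exceed the cell carrying capacity (most generous species present)
    cap = np.where(
        (state.biomass > 0).any(axis=1).any(axis=0), maxagb_cell.max(axis=0), np.inf
    )
    inc_tot = increments.sum(axis=(0, 1))
    room = np.maximum(cap - total, 0.0)
    scale = np.where(inc_tot > room, np.where(inc_tot > 0, room / np.maximum(inc_tot, 1e-12), 0.0), 1.0)
    state.biomass += increments * scale[None, None, :]

    # (4) establishment
    total = state.biomass.sum(axis=(0, 1))
    for s, code in enumerate(state.species):
        tr = traits[code]
        sep = dyn_tables["sep"][s, lt]
        if not np.any(sep > 0):
            continue
        sources = disperse_seeds(state, code, traits, rng)
        if not sources.any():
            continue
        occupancy = total / np.maximum(maxagb_cell[s], 1e-9)
        light_ok = occupancy <= light_thresholds[tr.shade_tolerance - 1]
        establish = sources & light_ok & (rng.random(state.n_cells) < sep)
        if establish.any():
            state.biomass[s, 1, establish] += regen_biomass

    state.year += ts
    burned = state.time_since_fire >= 0
    state.time_since_fire[burned] += ts
    return state


# ---------------------------------------------------------------------------
# fire
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FireRegimeParams:
    """Fire regime of every fire region for one climate state.

    ``annual_burn_rate`` is the expected fraction of the region burned per
    year, ``mean_fire_size`` the mean of the (lognormal) fire-size
    distribution in hectares.  The expected number of fires per year in a
    region is ``annual_burn_rate * region_area / mean_fire_size``.
    """

    annual_burn_rate: Mapping[int, float]
    mean_fire_size: Mapping[int, float]
    size_cv: float = 1.0
    spread_prob: float = 1.0

    def fire_occurrence(self, region: int, region_area: float) -> float:
        """Expected fires per year in a region of ``region_area`` hectares."""
        return (
            self.annual_burn_rate[region] * region_area / self.mean_fire_size[region]
        )


def build_fire_regime(
    cfg: Config, scenario: str, period: str, regions: Sequence[int]
) -> FireRegimeParams:
    """Resolve per-region fire parameters for one scenario and period.

    Under baseline (or ``period == "baseline"``) the configured baseline
    rates apply; under an RCP pathway the burn rate and mean fire size are
    scaled linearly in the period's position along the century, up to the
    configured end-of-century multipliers at full forcing.
    """
    fc = cfg.fire
    base_rate = {
        r: (fc.region_burn_rates or {}).get(r, fc.annual_burn_rate) for r in regions
    }
    if scenario == "baseline" or period == "baseline":
        mult_r = mult_s = 1.0
    else:
        phase = PERIOD_PHASE[period]
        force = FORCING[scenario]
        mult_r = 1.0 + (fc.rate_multiplier_max - 1.0) * force * phase
        mult_s = 1.0 + (fc.size_multiplier_max - 1.0) * force * phase
    return FireRegimeParams(
        annual_burn_rate={r: base_rate[r] * mult_r for r in regions},
        mean_fire_size={r: fc.mean_fire_size * mult_s for r in regions},
        size_cv=fc.size_cv,
        spread_prob=fc.spread_prob,
    )


def _grow_fire(
    ignition: int,
    target_cells: int,
    allowed: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
    spread_prob: float,
) -> list[int]:
    """Grow one fire from an ignition cell by stochastic neighbour accretion.

    4-neighbour spread restricted to ``allowed`` cells (same fire region,
    not yet burned this step); stops at the target size, the region edge,
    or when no unburned neighbours remain.
    """
    n_rows, n_cols = shape
    burned = [ignition]
    in_fire = {ignition}
    frontier = [ignition]
    while len(burned) < target_cells and frontier:
        i = rng.integers(len(frontier))
        cell = frontier[i]
        r, c = divmod(cell, n_cols)
        neighbours = []
        if r > 0:
            neighbours.append(cell - n_cols)
        if r < n_rows - 1:
            neighbours.append(cell + n_cols)
        if c > 0:
            neighbours.append(cell - 1)
        if c < n_cols - 1:
            neighbours.append(cell + 1)
        candidates = [
            nb for nb in neighbours if nb not in in_fire and allowed[nb]
        ]
        if not candidates:
            frontier[i] = frontier[-1]
            frontier.pop()
            continue
        for nb in candidates:
            if len(burned) >= target_cells:
                break
            if spread_prob >= 1.0 or rng.random() < spread_prob:
                burned.append(nb)
                in_fire.add(nb)
                frontier.append(nb)
    return burned


def simulate_fire(
    state: LandscapeState,
    regime: FireRegimeParams,
    traits: Mapping[str, SpeciesTraits],
    rng: np.random.Generator,
    regen_biomass: float = 0.5,
) -> tuple[LandscapeState, np.ndarray]:
    """Simulate one timestep of stochastic fire (in place).

    Per region the number of fires is Poisson with mean ``timestep *
    fire_occurrence``; fire sizes are lognormal with the regime's mean.
    Burned cells lose all cohorts except post-fire regeneration: serotinous
    species re-establish where a mature cohort was present before the burn,
    resprouters where any cohort was present.  ``time_since_fire`` resets to
    0 and the pre-fire stand age and conifer fraction are recorded.
    """
    grid = state.grid
    ts = grid.timestep
    shape = (grid.n_rows, grid.n_cols)
    burned_mask = np.zeros(state.n_cells, dtype=bool)
    regions = np.unique(state.fire_region)

    sigma2 = np.log(1.0 + regime.size_cv**2)
    sigma = np.sqrt(sigma2)

    for region in regions:
        rate = regime.annual_burn_rate[int(region)]
        if rate <= 0:
            continue
        region_mask = state.fire_region == region
        region_area = region_mask.sum() * grid.cell_area
        occ = regime.fire_occurrence(int(region), region_area)
        n_fires = rng.poisson(ts * occ)
        if n_fires == 0:
            continue
        mean_size = regime.mean_fire_size[int(region)]
        mu = np.log(mean_size) - sigma2 / 2.0
        sizes = rng.lognormal(mu, sigma, n_fires)
        allowed = region_mask & ~burned_mask
        for size in sizes:
            candidates = np.flatnonzero(allowed)
            if candidates.size == 0:
                break
            ignition = int(candidates[rng.integers(candidates.size)])
            target_cells = max(1, int(round(size / grid.cell_area)))
            cells = _grow_fire(
                ignition, target_cells, allowed, shape, rng, regime.spread_prob
            )
            burned_mask[cells] = True
            allowed[cells] = False

    if burned_mask.any():
        idx = np.flatnonzero(burned_mask)
        pre_age = state.stand_age_map()[idx]
        pre_conifer = state.conifer_fraction_map(traits)[idx]
        pre_presence = state.biomass[:, :, idx] > 0

        state.pre_fire_age[idx] = pre_age
        state.pre_fire_conifer[idx] = pre_conifer
        state.time_since_fire[idx] = 0
        state.biomass[:, :, idx] = 0.0

        for s, code in enumerate(state.species):
            tr = traits[code]
            if tr.post_fire_regen is PostFireRegen.SEROTINY:
                mature_class = -(-tr.maturity_age // ts)
                source = pre_presence[s, mature_class:].any(axis=0)
            elif tr.post_fire_regen is PostFireRegen.RESPROUT:
                source = pre_presence[s].any(axis=0)
            else:
                continue
            state.biomass[s, 0, idx[source]] = regen_biomass

    return state, burned_mask


# ---------------------------------------------------------------------------
# spruce budworm
# ---------------------------------------------------------------------------

def sbw_outbreak_active(sim_year: int, params: SBWParams, timestep: int = 5) -> bool:
    """Is an outbreak active during the step beginning at ``sim_year``
    (years since simulation start)?

    Outbreaks start at ``phase`` and every ``recurrence`` years thereafter,
    each lasting ``max_duration`` years.
    """
    if sim_year < params.phase:
        return False
    offset = (sim_year - params.phase) % params.recurrence
    return offset < params.max_duration


def apply_sbw(
    state: LandscapeState,
    params: SBWParams,
    rng: np.random.Generator,
    sim_year: int,
) -> LandscapeState:
    """Apply one timestep of spruce budworm mortality (in place).

    During active outbreak steps, host cohorts lose a biomass fraction that
    increases with cohort age (young/mid/old classes at <30, 30-60, >60 yr)
    and decreases down the host ranking; non-hosts are untouched.
    """
    if not sbw_outbreak_active(sim_year, params, state.grid.timestep):
        return state
    ages = state.class_ages
    age_band = np.digitize(ages, [30, 61])  # 0: <30, 1: 30-60, 2: >60
    base = np.asarray(params.age_mortality)[age_band]  # (age_class,)
    for rank, code in enumerate(params.host_ranking):
        if code not in state.species:
            continue
        s = state.species_index(code)
        frac = base * params.rank_severity[rank]
        state.biomass[s] *= (1.0 - frac)[:, None]
    state.biomass[state.biomass < _TINY_BIOMASS] = 0.0
    return state


# ---------------------------------------------------------------------------
# harvest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarvestPrescription:
    """Harvest rule for one management area."""

    management_area: int
    target_area: float  # hectares per timestep
    prescription: str  # clearcut | partial_low | partial_high
    eligibility_age: int = 60
    tenure: str = "public"
    removal_bounds: tuple[float, float] = (1.0, 1.0)  # for partial classes

    def __post_init__(self) -> None:
        if self.target_area < 0:
            raise ValueError("target_area must be non-negative")
        if self.prescription not in ("clearcut", "partial_low", "partial_high"):
            raise ValueError(f"unknown prescription {self.prescription!r}")
        lo, hi = self.removal_bounds
        if not 0 <= lo <= hi <= 1:
            raise ValueError("removal bounds must satisfy 0 <= lo <= hi <= 1")


def build_prescriptions(cfg: Config, state: LandscapeState) -> list[HarvestPrescription]:
    """Constant-area prescriptions per management area.

    Public areas are clearcut; private areas alternate between low- and
    high-level partial harvesting.  The per-step target is ``annual_rate *
    area * timestep``.
    """
    out = []
    for ma in np.unique(state.management_area):
        cells = state.management_area == ma
        area = cells.sum() * state.grid.cell_area
        tenure = "private" if np.any(state.land_tenure[cells] == 1) else "public"
        if tenure == "public":
            prescription, bounds = "clearcut", (1.0, 1.0)
        elif int(ma) % 2 == 0:
            prescription, bounds = "partial_low", cfg.harvest.partial_low
        else:
            prescription, bounds = "partial_high", cfg.harvest.partial_high
        out.append(
            HarvestPrescription(
                management_area=int(ma),
                target_area=cfg.harvest.annual_rate * area * state.grid.timestep,
                prescription=prescription,
                eligibility_age=cfg.harvest.eligibility_age,
                tenure=tenure,
                removal_bounds=bounds,
            )
        )
    return out


def apply_harvest(
    state: LandscapeState,
    prescriptions: Sequence[HarvestPrescription],
    rng: np.random.Generator,
) -> tuple[LandscapeState, np.ndarray, pd.DataFrame]:
    """Apply one timestep of harvesting (in place).

    Only cells containing a cohort strictly older than the eligibility age
    may be cut.  Cells are drawn at random among eligible ones until the
    constant area target is met or eligible cells run out (the shortfall is
    reported).  Clearcutting removes every cohort except those aged 0-5 yr;
    partial prescriptions remove a biomass fraction drawn uniformly within
    the class bounds, proportionally across cohorts.
    """
    grid = state.grid
    ts = grid.timestep
    ages = state.class_ages
    mask = np.zeros(state.n_cells, dtype=bool)
    records = []
    for p in prescriptions:
        in_ma = state.management_area == p.management_area
        old_classes = ages > p.eligibility_age
        eligible = in_ma & (state.biomass[:, old_classes, :] > 0).any(axis=(0, 1))
        n_target = int(round(p.target_area / grid.cell_area))
        candidates = np.flatnonzero(eligible)
        n_cut = min(n_target, candidates.size)
        if n_cut > 0:
            chosen = rng.choice(candidates, size=n_cut, replace=False)
            if p.prescription == "clearcut":
                keep = ages <= ts  # the 0-5 yr cohort survives
                cut_classes = np.flatnonzero(~keep)
                state.biomass[
                    np.ix_(np.arange(len(state.species)), cut_classes, chosen)
                ] = 0.0
            else:
                removal = rng.uniform(*p.removal_bounds, size=n_cut)
                state.biomass[:, :, chosen] *= 1.0 - removal[None, None, :]
                state.biomass[state.biomass < _TINY_BIOMASS] = 0.0
            mask[chosen] = True
        records.append(
            {
                "management_area": p.management_area,
                "prescription": p.prescription,
                "target_area": p.target_area,
                "harvested_area": n_cut * grid.cell_area,
                "shortfall": max(p.target_area - n_cut * grid.cell_area, 0.0),
            }
        )
    return state, mask, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# climate switching and full runs
# ---------------------------------------------------------------------------

def update_climate_period(year: int, scenario: str) -> str:
    """Map a calendar year to its climate period key.

    The baseline scenario always maps to ``"baseline"``; otherwise the
    century splits into 2000-2010, 2011-2040, 2041-2070 and 2071-2100.
    """
    if scenario == "baseline":
        return "baseline"
    if year <= 2010:
        return PERIODS[0]
    if year <= 2040:
        return PERIODS[1]
    if year <= 2070:
        return PERIODS[2]
    return PERIODS[3]


@dataclass(frozen=True)
class Toggles:
    """Factorial switches: harvesting on/off, and whether the fire regime
    and the stand-scale parameters follow the climate scenario or stay at
    baseline calibration."""

    harvest: bool = True
    fire_climate: bool = True
    stand_climate: bool = True


@dataclass
class Snapshot:
    """Habitat-relevant layers retained at one timestep."""

    year: int
    grid: GridSpec
    stand_age: np.ndarray
    conifer_fraction: np.ndarray
    time_since_fire: np.ndarray
    pre_fire_age: np.ndarray
    pre_fire_conifer: np.ndarray
    species_biomass_mean: dict[str, float]
    burned_area: float = 0.0
    harvested_area: float = 0.0


@dataclass
class SimulationResult:
    grid: GridSpec
    species: tuple[str, ...]
    scenario: str
    toggles: Toggles
    seed: int
    snapshots: list[Snapshot]
    log: pd.DataFrame
    final_state: LandscapeState | None = None


STREAMS = ("fire", "harvest", "establishment", "sbw")


def named_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent random stream per stochastic process."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(STREAMS, children)}


def _snapshot(
    state: LandscapeState,
    traits: Mapping[str, SpeciesTraits],
    burned_area: float = 0.0,
    harvested_area: float = 0.0,
) -> Snapshot:
    per_sp = state.species_biomass_map().mean(axis=1)
    return Snapshot(
        year=state.year,
        grid=state.grid,
        stand_age=state.stand_age_map(),
        conifer_fraction=state.conifer_fraction_map(traits),
        time_since_fire=state.time_since_fire.copy(),
        pre_fire_age=state.pre_fire_age.copy(),
        pre_fire_conifer=state.pre_fire_conifer.copy(),
        species_biomass_mean={c: float(b) for c, b in zip(state.species, per_sp)},
        burned_area=burned_area,
        harvested_area=harvested_area,
    )


def run_simulation(
    initial: LandscapeState,
    cfg: Config,
    scenario: str,
    toggles: Toggles = Toggles(),
    seed: int = 0,
    dyn: DynamicInputs | None = None,
    keep_final_state: bool = False,
    fire_rate_override: Callable[[int, str], float] | None = None,
) -> SimulationResult:
    """Run the full model over the configured horizon.

    Per 5-yr step: climate-period lookup (respecting the toggles), cohort
    succession, fire, spruce budworm (always on, as a background
    disturbance), and harvest if toggled on.  Snapshots of habitat-relevant
    layers are retained at every step including the initial one.  Fully
    reproducible from ``seed``.  ``fire_rate_override(sim_year, period)``,
    when given, returns a multiplier applied to all regions' burn rates for
    the step beginning at that simulation year (used for mid-run regime
    interventions).
    """
    state = initial.copy()
    traits = cfg.species
    if dyn is None:
        dyn = generate_dynamic_inputs(cfg, scenario)
    rngs = named_streams(seed)
    prescriptions = build_prescriptions(cfg, state) if toggles.harvest else []
    regions = [int(r) for r in np.unique(state.fire_region)]
    ts = cfg.grid.timestep

    snapshots = [_snapshot(state, traits)]
    log_rows = []
    for year in cfg.grid.years[:-1]:
        step_end = int(year) + ts
        stand_period = (
            update_climate_period(step_end, scenario)
            if toggles.stand_climate
            else "baseline"
        )
        fire_period = (
            update_climate_period(step_end, scenario)
            if toggles.fire_climate
            else "baseline"
        )
        tables = dyn.for_period(stand_period)
        regime = build_fire_regime(cfg, scenario, fire_period, regions)
        if fire_rate_override is not None:
            mult = fire_rate_override(int(year) - cfg.grid.origin_year, fire_period)
            regime = FireRegimeParams(
                annual_burn_rate={
                    r: v * mult for r, v in regime.annual_burn_rate.items()
                },
                mean_fire_size=regime.mean_fire_size,
                size_cv=regime.size_cv,
                spread_prob=regime.spread_prob,
            )

        step_succession(
            state,
            tables,
            traits,
            rngs["establishment"],
            light_thresholds=cfg.succession.light_thresholds,
            regen_biomass=cfg.succession.regen_biomass,
        )
        state, burned = simulate_fire(
            state, regime, traits, rngs["fire"], regen_biomass=cfg.succession.regen_biomass
        )
        apply_sbw(state, cfg.sbw, rngs["sbw"], int(year) - cfg.grid.origin_year)
        harvested_area = 0.0
        if toggles.harvest:
            state, hmask, report = apply_harvest(state, prescriptions, rngs["harvest"])
            harvested_area = float(report["harvested_area"].sum())
        burned_area = float(burned.sum() * cfg.grid.cell_area)
        snapshots.append(_snapshot(state, traits, burned_area, harvested_area))
        log_rows.append(
            {
                "year": step_end,
                "burned_area": burned_area,
                "harvested_area": harvested_area,
                "stand_period": stand_period,
                "fire_period": fire_period,
            }
        )

    return SimulationResult(
        grid=cfg.grid,
        species=state.species,
        scenario=scenario,
        toggles=toggles,
        seed=seed,
        snapshots=snapshots,
        log=pd.DataFrame(log_rows),
        final_state=state if keep_final_state else None,
    )
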