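"""Synthetic boreal landscapes and climate-sensitive growth parameters.

This module stands in for the inventory/remote-sensing initialization and the
gap-model-derived parameter sets a regional application would use.  It
produces landscapes with the statistical structure the analysis assumes:

* a latitudinal composition gradient (conifer share rising northward),
* a negative-exponential stand-age distribution, the stationary age
  distribution under a constant-rate stand-replacing fire regime, with mean
  equal to the configured fire cycle,
* zonation into horizontal-band fire regions and management areas, with a
  southern private-tenure fringe,
* per species x landtype x climate-period tables of establishment
  probability (SEP), maximum annual net primary productivity (maxANPP,
  kg/ha/yr) and maximum aboveground biomass (maxAGB, t/ha), with
  multiplicative climate trends whose magnitude grows with radiative
  forcing (conifers decline, warm-adapted deciduous species gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import Config, FORCING, PERIODS, PERIOD_PHASE, SCENARIOS
from .core import GridSpec, LandscapeState, SpeciesTraits

__all__ = [
    "DynamicInputs",
    "generate_initial_landscape",
    "generate_dynamic_inputs",
    "truncated_exponential_mean",
    "DEFAULT_MAX_AGB",
    "DEFAULT_MAX_ANPP",
]

#: Species-level asymptotic aboveground biomass (t/ha) on an average
#: landtype; broadly representative of closed-crown eastern boreal stands.
DEFAULT_MAX_AGB: Mapping[str, float] = {
    "ABIE.BAL": 110.0,
    "ACER.RUB": 110.0,
    "ACER.SAH": 150.0,
    "BETU.ALL": 140.0,
    "BETU.PAP": 100.0,
    "FAGU.GRA": 150.0,
    "LARI.LAR": 80.0,
    "PICE.GLA": 120.0,
    "PICE.MAR": 90.0,
    "PICE.RUB": 130.0,
    "PINU.BAN": 80.0,
    "PINU.RES": 120.0,
    "PINU.STR": 150.0,
    "POPU.TRE": 130.0,
    "QUER.RUB": 140.0,
    "THUJ.OCC": 120.0,
    "TSUG.CAN": 150.0,
}

#: Free-growth maximum annual net primary productivity (kg/ha/yr).
DEFAULT_MAX_ANPP: Mapping[str, float] = {
    code: agb * 30.0 for code, agb in DEFAULT_MAX_AGB.items()
}


@dataclass
class DynamicInputs:
    """SEP / maxANPP / maxAGB per species x landtype x climate period.

    ``tables`` maps a period key (``"baseline"`` or one of the four
    climate periods) to ``{"sep": (S, L), "maxanpp": (S, L), "maxagb":
    (S, L)}`` arrays.  ``bias_scalars`` are per-species multipliers on
    maxANPP/maxAGB (a configurable stand-in for landscape-level bias
    correction of the growth parameters; default 1).
    """

    species: tuple[str, ...]
    n_landtypes: int
    scenario: str
    tables: dict[str, dict[str, np.ndarray]]
    bias_scalars: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bias_scalars is None:
            self.bias_scalars = np.ones(len(self.species))
        shape = (len(self.species), self.n_landtypes)
        for period, tbl in self.tables.items():
            for name in ("sep", "maxanpp", "maxagb"):
                arr = tbl[name]
                if arr.shape != shape:
                    raise ValueError(f"{period}/{name}: expected shape {shape}")
                if np.any(arr < 0):
                    raise ValueError(f"{period}/{name}: negative values")
            if np.any(tbl["sep"] > 1):
                raise ValueError(f"{period}/sep: probabilities above 1")

    def for_period(self, period: str) -> dict[str, np.ndarray]:
        """Tables for one period, with bias scalars applied to growth terms."""
        tbl = self.tables[period]
        scal = self.bias_scalars[:, None]
        return {
            "sep": tbl["sep"],
            "maxanpp": tbl["maxanpp"] * scal,
            "maxagb": tbl["maxagb"] * scal,
        }


def _landtype_factor(n_landtypes: int) -> np.ndarray:
    """Deterministic site-quality gradient across landtypes (mean ~ 1)."""
    if n_landtypes == 1:
        return np.ones(1)
    return 0.85 + 0.3 * np.arange(n_landtypes) / (n_landtypes - 1)


def generate_dynamic_inputs(cfg: Config, scenario: str) -> DynamicInputs:
    """Build the climate-sensitive growth/establishment tables.

    The baseline table uses each species' baseline SEP and the default
    maxANPP/maxAGB scaled by a landtype site-quality factor.  For RCP
    scenarios a multiplicative trend is applied per period: conifer
    parameters decline (black spruce more steeply) and deciduous parameters
    rise, linearly in the period's position along the century and in the
    scenario's forcing strength, so magnitudes order RCP2.6 < RCP4.5 <
    RCP8.5.  SEP is clamped to [0, 1] after trend application.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    pool = tuple(cfg.synthetic.species_pool)
    L = cfg.synthetic.n_landtypes
    lt = _landtype_factor(L)[None, :]
    traits = cfg.species

    sep0 = np.array([traits[s].sep_baseline for s in pool])[:, None] * np.ones((1, L))
    anpp0 = np.array([DEFAULT_MAX_ANPP[s] for s in pool])[:, None] * lt
    agb0 = np.array([DEFAULT_MAX_AGB[s] for s in pool])[:, None] * lt

    base = {"sep": sep0.copy(), "maxanpp": anpp0.copy(), "maxagb": agb0.copy()}
    tables = {"baseline": base}

    force = FORCING[scenario]
    tr = cfg.climate
    end_mult = np.array(
        [
            1.0
            - force
            * (
                tr.conifer_decline
                + (tr.black_spruce_extra_decline if s == "PICE.MAR" else 0.0)
            )
            if traits[s].is_conifer
            else 1.0 + force * tr.deciduous_gain
            for s in pool
        ]
    )[:, None]
    for period in PERIODS:
        mult = 1.0 + (end_mult - 1.0) * PERIOD_PHASE[period]
        sep = sep0 * (mult if tr.sep_follows_growth else 1.0)
        tables[period] = {
            "sep": np.clip(sep, 0.0, 1.0),
            "maxanpp": anpp0 * mult,
            "maxagb": agb0 * mult,
        }
    return DynamicInputs(
        species=pool, n_landtypes=L, scenario=scenario, tables=tables
    )


def truncated_exponential_mean(mean: float, upper: float) -> float:
    """Mean of an Exp(mean) distribution right-truncated at ``upper``.

    Closed form: m - upper * exp(-upper/m) / (1 - exp(-upper/m)).
    """
    z = upper / mean
    return mean - upper * np.exp(-z) / (1.0 - np.exp(-z))


def _band_labels(n_rows: int, n_bands: int) -> np.ndarray:
    """Contiguous horizontal bands of near-equal height, label per row."""
    return np.minimum((np.arange(n_rows) * n_bands) // n_rows, n_bands - 1)


def generate_initial_landscape(
    cfg: Config, seed: int | None = None, dyn: DynamicInputs | None = None
) -> LandscapeState:
    """Generate a reproducible initial landscape.

    Stand ages are negative-exponential with mean
    ``synthetic.age_distribution_mean`` (truncated at species longevity and
    floored to the timestep); the probability that a cell is
    conifer-dominated interpolates linearly from the southern to the
    northern endpoint of ``synthetic.conifer_gradient`` (row 0 is the
    northern edge); fire regions and management areas are contiguous
    horizontal bands.  Initial cohort biomass follows a saturating ramp in
    age toward ``initial_stocking`` x maxAGB.
    """
    syn = cfg.synthetic
    syn.validate()
    grid = cfg.grid
    if seed is None:
        seed = syn.rng_seed
    rng = np.random.default_rng(seed)
    if dyn is None:
        dyn = generate_dynamic_inputs(cfg, "baseline")

    pool = list(syn.species_pool)
    weights = np.array([syn.species_pool[s] for s in pool], float)
    traits = cfg.species
    conif = np.array([traits[s].is_conifer for s in pool])
    if not conif.any() or conif.all():
        # degenerate pools are allowed; the gradient then has no effect on
        # the conifer/deciduous split, only on ages and zonation
        pass

    state = LandscapeState(
        grid,
        species=pool,
        max_longevity=max(traits[s].longevity for s in pool),
    )

    rows = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    state.fire_region = _band_labels(grid.n_rows, syn.n_fire_regions)[
        np.repeat(np.arange(grid.n_rows), grid.n_cols)
    ].astype(np.int16)
    ma_rows = _band_labels(grid.n_rows, syn.n_management_areas)
    state.management_area = ma_rows[rows].astype(np.int16)
    # southernmost management areas are private tenure
    n_private = int(round(syn.private_fraction * syn.n_management_areas))
    if syn.private_fraction > 0:
        n_private = max(n_private, 1)
    private_mas = set(range(syn.n_management_areas - n_private, syn.n_management_areas))
    state.land_tenure = np.isin(state.management_area, list(private_mas)).astype(np.int8)
    state.landtype = rng.integers(0, syn.n_landtypes, grid.n_cells).astype(np.int16)

    # composition: conifer probability by latitude (row 0 = north)
    south, north = syn.conifer_gradient
    frac_north = 1.0 - rows / max(grid.n_rows - 1, 1)
    p_conifer = south + (north - south) * frac_north
    take_conifer = rng.random(grid.n_cells) < p_conifer

    def _draw_species(group_mask: np.ndarray, k: int) -> np.ndarray:
        w = weights * group_mask
        if w.sum() == 0:
            w = weights.copy()
        return rng.choice(len(pool), size=k, p=w / w.sum())

    n = grid.n_cells
    dominant = np.empty(n, dtype=int)
    idx_c = np.flatnonzero(take_conifer)
    idx_d = np.flatnonzero(~take_conifer)
    if idx_c.size:
        dominant[idx_c] = _draw_species(conif.astype(float), idx_c.size)
    if idx_d.size:
        dominant[idx_d] = _draw_species((~conif).astype(float), idx_d.size)

    ages_raw = rng.exponential(syn.age_distribution_mean, n)
    longevity = np.array([traits[s].longevity for s in pool])
    ages = np.minimum(ages_raw, longevity[dominant])
    ts = grid.timestep
    age_class = np.maximum((ages // ts).astype(int), 1)

    base = dyn.for_period("baseline")
    maxagb = base["maxagb"][dominant, state.landtype]  # (cells,)
    age_yr = age_class * ts
    ramp = age_yr / (age_yr + 40.0)
    jitter = rng.uniform(0.8, 1.2, n)
    biom = np.minimum(syn.initial_stocking * maxagb * ramp * jitter, maxagb)
    state.biomass[dominant, age_class, np.arange(n)] = biom

    # a secondary, younger cohort in a fraction of cells adds mixedness
    second = rng.random(n) < 0.4
    idx2 = np.flatnonzero(second)
    if idx2.size:
        sp2 = rng.choice(len(pool), size=idx2.size, p=weights / weights.sum())
        ac2 = np.maximum(age_class[idx2] // 2, 1)
        same = sp2 == dominant[idx2]
        ac2[same] = np.maximum(ac2[same] - 1, 1)
        cap = base["maxagb"][sp2, state.landtype[idx2]]
        room = np.maximum(cap - biom[idx2], 0.0)
        b2 = np.minimum(0.2 * cap * (ac2 * ts) / (ac2 * ts + 40.0), room)
        state.biomass[sp2, ac2, idx2] += b2

    return state
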