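"""Shared data model for the landscape simulation and habitat analysis.

The landscape is a regular grid of cells (default 250 m resolution, 6.25 ha).
Vegetation in each cell is a set of *cohorts*: all trees of one species that
established in the same 5-yr timestep.  Cohort ages are therefore multiples
of the timestep.  For speed the full landscape is stored as a dense
``(species, age-class, cell)`` biomass array; per-cell cohort lists are
available as views for inspection and I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "SpeciesTraits",
    "Cohort",
    "LandscapeState",
    "HabitatType",
    "HabitatCoefficients",
    "DEFAULT_TRAITS",
    "DEFAULT_HABITAT_COEFFS",
    "stand_age",
    "conifer_fraction",
    "stand_age_map",
    "conifer_fraction_map",
]

NEVER_BURNED = -1


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and temporal conventions of a simulation."""

    n_rows: int
    n_cols: int
    cell_area: float = 6.25  # hectares (250 m cells)
    origin_year: int = 2000
    timestep: int = 5  # years
    horizon: int = 100  # years

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.timestep <= 0 or self.horizon % self.timestep != 0:
            raise ValueError("timestep must be positive and divide horizon")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def landscape_area(self) -> float:
        """Total area in hectares."""
        return self.n_cells * self.cell_area

    @property
    def cell_size_m(self) -> float:
        """Cell side length in metres (cells are square)."""
        return float(np.sqrt(self.cell_area * 1e4))

    @property
    def years(self) -> np.ndarray:
        """Calendar years of every snapshot, including the initial one."""
        return np.arange(
            self.origin_year, self.origin_year + self.horizon + 1, self.timestep
        )


class PostFireRegen(str, Enum):
    NONE = "none"
    RESPROUT = "resprout"
    SEROTINY = "serotiny"


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history traits of one tree species.

    ``shade_tolerance`` runs from 1 (least tolerant) to 5 (most tolerant);
    ``effective_dispersal`` is the distance (m) within which 95% of seeds
    fall, ``maximum_dispersal`` the hard dispersal limit.  ``growth_shape``
    and ``mortality_shape`` modulate the growth-rate ramp and the onset of
    senescence mortality as a cohort approaches ``longevity``.
    """

    code: str
    longevity: int
    maturity_age: int
    shade_tolerance: int
    effective_dispersal: float
    maximum_dispersal: float
    vegetative_regen: bool
    post_fire_regen: PostFireRegen
    growth_shape: float
    mortality_shape: float
    is_conifer: bool
    sep_baseline: float = 0.3  # mean establishment probability per 5-yr step

    def __post_init__(self) -> None:
        if not 0 < self.maturity_age < self.longevity:
            raise ValueError(f"{self.code}: need 0 < maturity_age < longevity")
        if not 1 <= self.shade_tolerance <= 5:
            raise ValueError(f"{self.code}: shade_tolerance must be in 1..5")
        if self.effective_dispersal > self.maximum_dispersal:
            raise ValueError(f"{self.code}: effective_dispersal > maximum_dispersal")
        if not 0 <= self.sep_baseline <= 1:
            raise ValueError(f"{self.code}: sep_baseline must be a probability")


def _t(code, lon, mat, shade, ed, md, veg, pfr, g, m, conifer, sep):
    return SpeciesTraits(
        code=code,
        longevity=lon,
        maturity_age=mat,
        shade_tolerance=shade,
        effective_dispersal=ed,
        maximum_dispersal=md,
        vegetative_regen=veg,
        post_fire_regen=PostFireRegen(pfr),
        growth_shape=g,
        mortality_shape=m,
        is_conifer=conifer,
        sep_baseline=sep,
    )


#: Life-history traits for the tree species of the eastern boreal/hemiboreal
#: transition: longevity, maturity age, shade tolerance (1-5), effective and
#: maximum seed dispersal (m), vegetative regeneration, post-fire regeneration
#: mode, growth/mortality curve shapes, conifer flag, and mean baseline
#: establishment probability per 5-yr step.
DEFAULT_TRAITS: Mapping[str, SpeciesTraits] = {
    s.code: s
    for s in [
        _t("ABIE.BAL", 150, 30, 5, 25, 160, False, "none", 0, 25, True, 0.48),
        _t("ACER.RUB", 150, 10, 3, 100, 200, True, "resprout", 0, 25, False, 0.31),
        _t("ACER.SAH", 300, 40, 5, 100, 200, True, "resprout", 1, 15, False, 0.30),
        _t("BETU.ALL", 300, 40, 3, 100, 400, True, "resprout", 1, 15, False, 0.29),
        _t("BETU.PAP", 150, 20, 2, 200, 5000, True, "resprout", 0, 25, False, 0.55),
        _t("FAGU.GRA", 250, 40, 5, 30, 3000, True, "none", 1, 15, False, 0.27),
        _t("LARI.LAR", 150, 40, 1, 50, 200, False, "none", 0, 25, True, 0.54),
        _t("PICE.GLA", 200, 30, 3, 100, 303, False, "none", 1, 15, True, 0.43),
        _t("PICE.MAR", 200, 30, 4, 80, 200, False, "serotiny", 1, 15, True, 0.36),
        _t("PICE.RUB", 300, 30, 4, 100, 303, False, "none", 1, 15, True, 0.25),
        _t("PINU.BAN", 150, 20, 1, 30, 100, False, "serotiny", 0, 25, True, 0.54),
        _t("PINU.RES", 200, 40, 2, 12, 275, False, "none", 1, 15, True, 0.32),
        _t("PINU.STR", 300, 20, 3, 100, 250, False, "none", 1, 15, True, 0.30),
        _t("POPU.TRE", 150, 20, 1, 1000, 5000, True, "resprout", 0, 25, False, 0.59),
        _t("QUER.RUB", 250, 30, 3, 30, 3000, True, "resprout", 1, 15, False, 0.28),
        _t("THUJ.OCC", 300, 30, 5, 45, 60, False, "none", 1, 15, True, 0.26),
        _t("TSUG.CAN", 300, 60, 5, 30, 100, False, "none", 1, 15, True, 0.21),
    ]
}


class Cohort(NamedTuple):
    """One species cohort in one cell: species code, age (yr), biomass (t/ha)."""

    species: str
    age: int
    biomass: float


class HabitatType(str, Enum):
    """Woodpecker habitat classes.

    Five parameterized habitat types plus ``NON_HABITAT`` (everything else,
    zero productivity).
    """

    OLD_CONIF_UNBURNED = "OLD_CONIF_UNBURNED"
    OLD_MIXED_UNBURNED = "OLD_MIXED_UNBURNED"
    BURNED_OLD_CONIF_1_5 = "BURNED_OLD_CONIF_1_5"
    BURNED_YOUNG_CONIF_1_5 = "BURNED_YOUNG_CONIF_1_5"
    BURNED_OLD_CONIF_6_10 = "BURNED_OLD_CONIF_6_10"
    NON_HABITAT = "NON_HABITAT"


#: Integer codes used in habitat rasters, in a fixed order.
HABITAT_CODES: Mapping[HabitatType, int] = {
    HabitatType.NON_HABITAT: 0,
    HabitatType.OLD_CONIF_UNBURNED: 1,
    HabitatType.OLD_MIXED_UNBURNED: 2,
    HabitatType.BURNED_OLD_CONIF_1_5: 3,
    HabitatType.BURNED_YOUNG_CONIF_1_5: 4,
    HabitatType.BURNED_OLD_CONIF_6_10: 5,
}


@dataclass(frozen=True)
class HabitatCoefficients:
    """Home-range size (ha) and mean productivity (fledglings/home-range/yr)
    for each parameterized habitat type."""

    home_range: Mapping[HabitatType, float]
    productivity: Mapping[HabitatType, float]

    def __post_init__(self) -> None:
        required = set(HabitatType) - {HabitatType.NON_HABITAT}
        for name, table in (("home_range", self.home_range), ("productivity", self.productivity)):
            missing = required - set(table)
            if missing:
                raise ValueError(f"{name} missing habitat types: {sorted(missing)}")
        if any(v <= 0 for v in self.home_range.values()):
            raise ValueError("home ranges must be positive")
        if any(v < 0 for v in self.productivity.values()):
            raise ValueError("productivities must be non-negative")


DEFAULT_HABITAT_COEFFS = HabitatCoefficients(
    home_range={
        HabitatType.OLD_CONIF_UNBURNED: 150.0,
        HabitatType.OLD_MIXED_UNBURNED: 300.0,
        HabitatType.BURNED_OLD_CONIF_1_5: 40.0,
        HabitatType.BURNED_YOUNG_CONIF_1_5: 100.0,
        HabitatType.BURNED_OLD_CONIF_6_10: 200.0,
    },
    productivity={
        HabitatType.OLD_CONIF_UNBURNED: 1.5,
        HabitatType.OLD_MIXED_UNBURNED: 1.0,
        HabitatType.BURNED_OLD_CONIF_1_5: 1.4,
        HabitatType.BURNED_YOUNG_CONIF_1_5: 0.25,
        HabitatType.BURNED_OLD_CONIF_6_10: 0.4,
    },
)


class LandscapeState:
    """Full simulation state on a grid.

    Cohort biomass lives in ``biomass`` with shape
    ``(n_species, n_age_classes, n_cells)``; age class ``a`` holds cohorts of
    age ``a * timestep`` years.  ``time_since_fire`` is ``NEVER_BURNED`` (-1)
    for cells that have not burned during the simulation.  ``pre_fire_age``
    and ``pre_fire_conifer`` record the stand age and conifer biomass
    fraction at the moment of the last burn; they feed the classifier for
    recently burned habitat, where live biomass no longer reflects the
    pre-disturbance stand.
    """

    def __init__(
        self,
        grid: GridSpec,
        species: Sequence[str],
        max_longevity: int | None = None,
        year: int | None = None,
    ):
        self.grid = grid
        self.species = tuple(species)
        if max_longevity is None:
            max_longevity = max(DEFAULT_TRAITS[s].longevity for s in species)
        self.n_age_classes = max_longevity // grid.timestep + 1
        n = grid.n_cells
        self.biomass = np.zeros(
            (len(self.species), self.n_age_classes, n), dtype=np.float64
        )
        self.time_since_fire = np.full(n, NEVER_BURNED, dtype=np.int32)
        self.pre_fire_age = np.zeros(n, dtype=np.int32)
        self.pre_fire_conifer = np.zeros(n, dtype=np.float64)
        self.landtype = np.zeros(n, dtype=np.int16)
        self.fire_region = np.zeros(n, dtype=np.int16)
        self.management_area = np.zeros(n, dtype=np.int16)
        self.land_tenure = np.zeros(n, dtype=np.int8)  # 0 = public, 1 = private
        self.year = grid.origin_year if year is None else year

    # -- indexing helpers ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.grid.n_cells

    @property
    def class_ages(self) -> np.ndarray:
        """Age in years of every age class."""
        return np.arange(self.n_age_classes) * self.grid.timestep

    def species_index(self, code: str) -> int:
        return self.species.index(code)

    def copy(self) -> "LandscapeState":
        out = LandscapeState.__new__(LandscapeState)
        out.grid = self.grid
        out.species = self.species
        out.n_age_classes = self.n_age_classes
        out.biomass = self.biomass.copy()
        out.time_since_fire = self.time_since_fire.copy()
        out.pre_fire_age = self.pre_fire_age.copy()
        out.pre_fire_conifer = self.pre_fire_conifer.copy()
        out.landtype = self.landtype.copy()
        out.fire_region = self.fire_region.copy()
        out.management_area = self.management_area.copy()
        out.land_tenure = self.land_tenure.copy()
        out.year = self.year
        return out

    # -- cohort views --------------------------------------------------------
    def cohorts_at(self, cell: int) -> list[Cohort]:
        """Cohort list of one cell (flat index), ordered oldest first."""
        si, ai = np.nonzero(self.biomass[:, :, cell] > 0)
        order = np.argsort(-ai, kind="stable")
        ts = self.grid.timestep
        return [
            Cohort(self.species[s], int(a) * ts, float(self.biomass[s, a, cell]))
            for s, a in zip(si[order], ai[order])
        ]

    def set_cohorts(self, cell: int, cohorts: Iterable[Cohort]) -> None:
        self.biomass[:, :, cell] = 0.0
        ts = self.grid.timestep
        for c in cohorts:
            if c.age % ts != 0:
                raise ValueError(f"cohort age {c.age} not a multiple of timestep {ts}")
            if c.biomass < 0:
                raise ValueError("cohort biomass must be non-negative")
            self.biomass[self.species_index(c.species), c.age // ts, cell] += c.biomass

    def to_cohort_table(self) -> pd.DataFrame:
        """Long-format cohort table (cell_id, species, age, biomass)."""
        si, ai, ci = np.nonzero(self.biomass > 0)
        return pd.DataFrame(
            {
                "cell_id": ci,
                "species": [self.species[i] for i in si],
                "age": ai * self.grid.timestep,
                "biomass": self.biomass[si, ai, ci],
            }
        ).sort_values(["cell_id", "age", "species"], ignore_index=True)

    def load_cohort_table(self, table: pd.DataFrame) -> None:
        self.biomass[:] = 0.0
        ts = self.grid.timestep
        sidx = {code: i for i, code in enumerate(self.species)}
        for row in table.itertuples(index=False):
            self.biomass[sidx[row.species], int(row.age) // ts, int(row.cell_id)] += row.biomass

    # -- derived maps --------------------------------------------------------
    def presence(self) -> np.ndarray:
        """(species, age_class, cell) boolean cohort presence."""
        return self.biomass > 0

    def total_biomass_map(self) -> np.ndarray:
        """Total live biomass per cell, t/ha."""
        return self.biomass.sum(axis=(0, 1))

    def species_biomass_map(self) -> np.ndarray:
        """(species, cell) live biomass, t/ha."""
        return self.biomass.sum(axis=1)

    def stand_age_map(self) -> np.ndarray:
        """Stand age (max cohort age, yr) per cell; 0 where no cohorts."""
        present = (self.biomass > 0).any(axis=0)  # (age_class, cell)
        # highest occupied age class per cell
        rev = present[::-1]
        first = rev.argmax(axis=0)
        ages = (self.n_age_classes - 1 - first) * self.grid.timestep
        return np.where(present.any(axis=0), ages, 0).astype(np.int32)

    def conifer_fraction_map(self, traits: Mapping[str, SpeciesTraits]) -> np.ndarray:
        """Conifer share of live biomass per cell; 0 where biomass is 0."""
        mask = np.array([traits[s].is_conifer for s in self.species])
        per_sp = self.species_biomass_map()
        total = per_sp.sum(axis=0)
        conif = per_sp[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, conif / np.where(total > 0, total, 1.0), 0.0)
        return frac


# -- per-cell pure functions (reference semantics for the dense maps) --------

def stand_age(cell_cohorts: Sequence[Cohort]) -> int:
    """Stand age of a cell: age of its oldest cohort, 0 for an empty cell."""
    return max((c.age for c in cell_cohorts), default=0)


def conifer_fraction(
    cell_cohorts: Sequence[Cohort], traits: Mapping[str, SpeciesTraits]
) -> float:
    """Conifer share of the cell's live biomass; 0 when total biomass is 0."""
    total = sum(c.biomass for c in cell_cohorts)
    if total <= 0:
        return 0.0
    conif = sum(c.biomass for c in cell_cohorts if traits[c.species].is_conifer)
    return conif / total


def stand_age_map(state: LandscapeState) -> np.ndarray:
    return state.stand_age_map()


def conifer_fraction_map(
    state: LandscapeState, traits: Mapping[str, SpeciesTraits]
) -> np.ndarray:
    return state.conifer_fraction_map(traits)
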