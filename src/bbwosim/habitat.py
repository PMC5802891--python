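"""Woodpecker habitat classification, patch aggregation, and productivity.

Cells are classed by stand age, years post-fire and composition into five
habitat types (plus non-habitat), contiguous equal-class cells are merged
into patches, patches at least as large as the type's mean home range are
eligible, and potential productivity is the per-home-range fledgling
output summed over eligible patches.  For recently burned classes the
composition and age recorded at burn time are used, since post-fire live
biomass no longer describes the stand the burn created.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import HabitatConfig
from .core import (
    HABITAT_CODES,
    GridSpec,
    HabitatCoefficients,
    HabitatType,
    LandscapeState,
    SpeciesTraits,
)

__all__ = [
    "HabitatMap",
    "Patch",
    "HabitatPatchSet",
    "ProductivityReport",
    "classify_habitat",
    "classify_habitat_arrays",
    "aggregate_patches",
    "compute_productivity",
]

_CODE_TO_TYPE = {v: k for k, v in HABITAT_CODES.items()}


@dataclass
class HabitatMap:
    """Per-cell habitat labels (integer codes per ``HABITAT_CODES``)."""

    codes: np.ndarray  # (n_cells,) int8
    grid: GridSpec
    year: int

    def labels(self) -> np.ndarray:
        return np.array([_CODE_TO_TYPE[c].value for c in self.codes])

    def count(self, habitat: HabitatType) -> int:
        return int((self.codes == HABITAT_CODES[habitat]).sum())


def classify_habitat_arrays(
    stand_age: np.ndarray,
    conifer_fraction: np.ndarray,
    time_since_fire: np.ndarray,
    pre_fire_age: np.ndarray,
    pre_fire_conifer: np.ndarray,
    grid: GridSpec,
    habitat_cfg: HabitatConfig,
    year: int = 0,
) -> HabitatMap:
    """Classify cells into habitat types from layer arrays.

    Rules, in precedence order (thresholds from ``habitat_cfg``;
    "coniferous" means conifer fraction >= ``conif_threshold``, "mixed"
    between ``mixed_lower`` and the threshold):

    1. burned 1-5 yr ago: recently burned old (pre-fire age >= 80) or young
       (< 80) coniferous forest when the pre-fire composition was
       coniferous, otherwise non-habitat;
    2. burned 6-10 yr ago, pre-fire old and coniferous: older burned
       coniferous forest;
    3. unburned (or burned > 10 yr ago) stands aged >= 80: old coniferous
       or old mixed unburned forest by current composition;
    4. everything else: non-habitat.
    """
    tsf = time_since_fire
    codes = np.full(grid.n_cells, HABITAT_CODES[HabitatType.NON_HABITAT], dtype=np.int8)

    conif_t = habitat_cfg.conif_threshold
    mixed_lo = habitat_cfg.mixed_lower

    recent = (tsf >= 1) & (tsf <= 5)
    older_burn = (tsf >= 6) & (tsf <= 10)
    unburned = (tsf < 0) | (tsf > 10)

    pre_conif = pre_fire_conifer >= conif_t
    codes[recent & pre_conif & (pre_fire_age >= 80)] = HABITAT_CODES[
        HabitatType.BURNED_OLD_CONIF_1_5
    ]
    codes[recent & pre_conif & (pre_fire_age < 80)] = HABITAT_CODES[
        HabitatType.BURNED_YOUNG_CONIF_1_5
    ]
    codes[older_burn & pre_conif & (pre_fire_age >= 80)] = HABITAT_CODES[
        HabitatType.BURNED_OLD_CONIF_6_10
    ]

    old_now = unburned & (stand_age >= 80)
    codes[old_now & (conifer_fraction >= conif_t)] = HABITAT_CODES[
        HabitatType.OLD_CONIF_UNBURNED
    ]
    codes[
        old_now & (conifer_fraction >= mixed_lo) & (conifer_fraction < conif_t)
    ] = HABITAT_CODES[HabitatType.OLD_MIXED_UNBURNED]

    return HabitatMap(codes=codes, grid=grid, year=year)


def classify_habitat(state_or_snapshot, habitat_cfg: HabitatConfig, traits=None) -> HabitatMap:
    """Classify a ``LandscapeState`` or simulation ``Snapshot``."""
    obj = state_or_snapshot
    if isinstance(obj, LandscapeState):
        if traits is None:
            raise ValueError("classifying a LandscapeState requires the traits table")
        return classify_habitat_arrays(
            obj.stand_age_map(),
            obj.conifer_fraction_map(traits),
            obj.time_since_fire,
            obj.pre_fire_age,
            obj.pre_fire_conifer,
            obj.grid,
            habitat_cfg,
            year=obj.year,
        )
    # duck-typed Snapshot (carries its grid)
    return classify_habitat_arrays(
        obj.stand_age,
        obj.conifer_fraction,
        obj.time_since_fire,
        obj.pre_fire_age,
        obj.pre_fire_conifer,
        grid=obj.grid,
        habitat_cfg=habitat_cfg,
        year=obj.year,
    )


@dataclass(frozen=True)
class Patch:
    habitat: HabitatType
    cells: np.ndarray  # flat indices
    area: float  # hectares
    eligible: bool


@dataclass
class HabitatPatchSet:
    patches: list[Patch]
    grid: GridSpec
    year: int

    def eligible_count(self, habitat: HabitatType) -> int:
        return sum(1 for p in self.patches if p.habitat is habitat and p.eligible)

    def eligible_area(self, habitat: HabitatType) -> float:
        return sum(p.area for p in self.patches if p.habitat is habitat and p.eligible)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def aggregate_patches(
    habitat: HabitatMap,
    coeffs: HabitatCoefficients,
    connectivity: int = 4,
) -> HabitatPatchSet:
    """Merge contiguous equal-label cells into patches and flag eligibility.

    Connected components are computed per habitat label under rook (4) or
    queen (8) connectivity; a patch is eligible when its area (cell count x
    cell area) is at least the mean home-range size of its habitat type.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURES[connectivity]
    grid = habitat.grid
    img = habitat.codes.reshape(grid.n_rows, grid.n_cols)
    patches: list[Patch] = []
    for habitat_type, code in HABITAT_CODES.items():
        if habitat_type is HabitatType.NON_HABITAT:
            continue
        mask = img == code
        if not mask.any():
            continue
        labelled, n = ndimage.label(mask, structure=structure)
        flat = labelled.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        boundaries = np.searchsorted(sorted_labels, np.arange(1, n + 2))
        for k in range(n):
            cells = order[boundaries[k] : boundaries[k + 1]]
            area = cells.size * grid.cell_area
            patches.append(
                Patch(
                    habitat=habitat_type,
                    cells=np.sort(cells),
                    area=area,
                    eligible=area >= coeffs.home_range[habitat_type],
                )
            )
    return HabitatPatchSet(patches=patches, grid=grid, year=habitat.year)


@dataclass
class ProductivityReport:
    """Potential productivity per habitat type and in total.

    ``table`` has one row per habitat type: eligible patch count, potential
    productivity (fledglings/yr), density (fledglings/100 km2/yr) and
    relative contribution; ``degenerate`` flags a landscape with zero total
    productivity (contributions then reported as 0).
    """

    table: pd.DataFrame
    total_productivity: float
    total_density: float
    landscape_area: float
    degenerate: bool


def compute_productivity(
    patches: HabitatPatchSet,
    coeffs: HabitatCoefficients,
    landscape_area: float | None = None,
    count_mode: str = "patches",
) -> ProductivityReport:
    """Potential fledgling productivity from the eligible patch set.

    In the default ``"patches"`` mode each eligible patch contributes one
    home range's mean productivity (productivity = eligible patch count x
    per-home-range productivity).  In ``"home_ranges"`` mode each eligible
    patch contributes ``floor(area / home_range)`` home ranges, making the
    response monotone in habitat area even when patches merge or split.
    Densities are normalized per 100 km2 (10,000 ha).
    """
    if count_mode not in ("patches", "home_ranges"):
        raise ValueError("count_mode must be 'patches' or 'home_ranges'")
    if landscape_area is None:
        landscape_area = patches.grid.landscape_area
    rows = []
    for habitat_type in HABITAT_CODES:
        if habitat_type is HabitatType.NON_HABITAT:
            continue
        eligible = [
            p for p in patches.patches if p.habitat is habitat_type and p.eligible
        ]
        if count_mode == "patches":
            units = len(eligible)
        else:
            hr = coeffs.home_range[habitat_type]
            units = int(sum(int(p.area // hr) for p in eligible))
        prod = units * coeffs.productivity[habitat_type]
        rows.append(
            {
                "habitat": habitat_type.value,
                "eligible_patches": len(eligible),
                "units": units,
                "productivity": prod,
                "density": prod * 1e4 / landscape_area,
            }
        )
    table = pd.DataFrame(rows)
    total = float(table["productivity"].sum())
    degenerate = total <= 0
    table["relative_contribution"] = (
        0.0 if degenerate else table["productivity"] / total
    )
    return ProductivityReport(
        table=table,
        total_productivity=total,
        total_density=total * 1e4 / landscape_area,
        landscape_area=landscape_area,
        degenerate=degenerate,
    )
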