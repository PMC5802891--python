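"""Factorial simulation experiments and driver-importance statistics.

The design crosses three drivers of change — harvesting, climate-driven
change in the fire regime, and climate-driven change in stand-scale
parameters (SEP/maxANPP/maxAGB) — each at two levels (baseline vs.
projected / on vs. off), replicated with paired seeds, separately for each
climate pathway.  Driver importance is summarized three ways:

* omega-squared from a three-way factorial ANOVA on total potential
  productivity at each timestep:
  ``w2 = (SS_effect - df_effect * MS_error) / (MS_error + SS_tot)``
  (reported as computed, which can be slightly negative for null effects);
* Delta-Prod, the percentage difference in total potential productivity
  between the full model and the reduced model omitting one driver;
* Delta-B, the same percentage difference applied to one species' mean
  aboveground biomass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, SCENARIOS
from .core import HABITAT_CODES, HabitatType
from .flm import SimulationResult, Toggles, run_simulation
from .habitat import aggregate_patches, classify_habitat, compute_productivity
from .synthetic import generate_dynamic_inputs, generate_initial_landscape

__all__ = [
    "ExperimentDesign",
    "AnovaDecomposition",
    "DegenerateDataError",
    "EFFECTS",
    "DRIVERS",
    "analyze_run",
    "run_factorial",
    "compute_anova",
    "omega_squared",
    "delta_prod",
    "delta_biomass",
    "sensitivity_table",
]

DRIVERS = ("harvest", "fire", "stand")
EFFECTS = (
    "harvest",
    "fire",
    "stand",
    "harvest:fire",
    "harvest:stand",
    "fire:stand",
    "harvest:fire:stand",
)

_FACTOR_COLUMNS = {"harvest": "harvest", "fire": "fire_climate", "stand": "stand_climate"}


class DegenerateDataError(ValueError):
    """All responses identical: the variance decomposition is undefined."""


@dataclass(frozen=True)
class ExperimentDesign:
    """A full 2x2x2 factorial over the three drivers, per scenario.

    Replicate ``r`` uses seed ``seed_base + r`` for every toggle
    combination (paired design), so toggling one driver changes only that
    driver's random stream.
    """

    scenarios: tuple[str, ...] = ("rcp26", "rcp45", "rcp85")
    replicates: int = 5
    seed_base: int = 0

    def __post_init__(self) -> None:
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(self.seed_base + r for r in range(self.replicates))

    @property
    def n_runs(self) -> int:
        return 8 * self.replicates * len(self.scenarios)


def analyze_run(
    result: SimulationResult, cfg: Config, count_mode: str | None = None
) -> pd.DataFrame:
    """Habitat productivity series of one run: one row per snapshot.

    Columns: year, total productivity (fledglings/yr), total density
    (fledglings/100 km2/yr), per-habitat density and relative contribution,
    and per-species landscape-mean AGB (``agb_<code>``).
    """
    if count_mode is None:
        count_mode = cfg.habitat.count_mode
    rows = []
    for snap in result.snapshots:
        hmap = classify_habitat(snap, cfg.habitat)
        patches = aggregate_patches(
            hmap, cfg.habitat.coefficients, cfg.habitat.connectivity
        )
        report = compute_productivity(
            patches, cfg.habitat.coefficients, count_mode=count_mode
        )
        row = {
            "year": snap.year,
            "total_productivity": report.total_productivity,
            "total_density": report.total_density,
            "burned_area": snap.burned_area,
            "harvested_area": snap.harvested_area,
        }
        for rec in report.table.itertuples(index=False):
            row[f"density_{rec.habitat}"] = rec.density
            row[f"contribution_{rec.habitat}"] = rec.relative_contribution
        for code, agb in snap.species_biomass_mean.items():
            row[f"agb_{code}"] = agb
        rows.append(row)
    return pd.DataFrame(rows)


def run_factorial(
    design: ExperimentDesign,
    cfg: Config,
    count_mode: str | None = None,
    progress=None,
) -> pd.DataFrame:
    """Run the full factorial and return a long results table.

    One row per run x timestep, with the scenario, the three toggle levels,
    the replicate, the productivity response and the per-species AGB.  The
    same synthetic initial landscape and seed are shared by all toggle
    combinations of a replicate.  Deterministic given the design.
    """
    frames = []
    run_id = 0
    for replicate, seed in enumerate(design.seeds):
        initial = generate_initial_landscape(cfg, seed=seed)
        for scenario in design.scenarios:
            dyn = generate_dynamic_inputs(cfg, scenario)
            for harvest, fire_on, stand_on in itertools.product(
                (True, False), repeat=3
            ):
                toggles = Toggles(
                    harvest=harvest, fire_climate=fire_on, stand_climate=stand_on
                )
                result = run_simulation(
                    initial, cfg, scenario, toggles=toggles, seed=seed, dyn=dyn
                )
                series = analyze_run(result, cfg, count_mode=count_mode)
                series.insert(0, "run_id", run_id)
                series.insert(1, "scenario", scenario)
                series.insert(2, "harvest", harvest)
                series.insert(3, "fire_climate", fire_on)
                series.insert(4, "stand_climate", stand_on)
                series.insert(5, "replicate", replicate)
                frames.append(series)
                run_id += 1
                if progress is not None:
                    progress(run_id, design.n_runs)
    return pd.concat(frames, ignore_index=True)


@dataclass
class AnovaDecomposition:
    """Balanced three-way ANOVA decomposition of one scenario x timestep."""

    ss: dict[str, float]  # per effect in EFFECTS
    df: dict[str, int]
    ss_error: float
    df_error: int
    ss_total: float

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def check_additivity(self, rtol: float = 1e-9) -> bool:
        total = sum(self.ss.values()) + self.ss_error
        return bool(np.isclose(total, self.ss_total, rtol=rtol, atol=1e-9))


def compute_anova(
    data: pd.DataFrame, response: str = "total_productivity"
) -> AnovaDecomposition:
    """Type-I sums of squares for the balanced 2x2x2 design with replication.

    ``data`` must contain boolean factor columns ``harvest``,
    ``fire_climate`` and ``stand_climate`` and one response value per run
    (a single timestep).  For a balanced design the type-I, II and III
    decompositions coincide and reduce to sums over cell and marginal
    means, which is what is computed here.  Unbalanced designs are
    rejected.
    """
    y = data[response].to_numpy(float)
    levels = [data[_FACTOR_COLUMNS[d]].to_numpy(bool) for d in DRIVERS]
    n_total = y.size
    counts = np.zeros((2, 2, 2), int)
    sums = np.zeros((2, 2, 2))
    sumsq = np.zeros((2, 2, 2))
    idx = tuple(lv.astype(int) for lv in levels)
    np.add.at(counts, idx, 1)
    np.add.at(sums, idx, y)
    np.add.at(sumsq, idx, y**2)
    n = counts.flat[0]
    if n < 2 or not np.all(counts == n):
        raise ValueError("design must be a balanced 2x2x2 with >= 2 replicates")

    grand = y.mean()
    cell_means = sums / n
    # marginal means over the other factors
    mA = cell_means.mean(axis=(1, 2))
    mB = cell_means.mean(axis=(0, 2))
    mC = cell_means.mean(axis=(0, 1))
    mAB = cell_means.mean(axis=2)
    mAC = cell_means.mean(axis=1)
    mBC = cell_means.mean(axis=0)

    ss = {}
    ss["harvest"] = 4 * n * float(((mA - grand) ** 2).sum())
    ss["fire"] = 4 * n * float(((mB - grand) ** 2).sum())
    ss["stand"] = 4 * n * float(((mC - grand) ** 2).sum())
    ss["harvest:fire"] = 2 * n * float(
        ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    )
    ss["harvest:stand"] = 2 * n * float(
        ((mAC - mA[:, None] - mC[None, :] + grand) ** 2).sum()
    )
    ss["fire:stand"] = 2 * n * float(
        ((mBC - mB[:, None] - mC[None, :] + grand) ** 2).sum()
    )
    interaction3 = (
        cell_means
        - mAB[:, :, None]
        - mAC[:, None, :]
        - mBC[None, :, :]
        + mA[:, None, None]
        + mB[None, :, None]
        + mC[None, None, :]
        - grand
    )
    ss["harvest:fire:stand"] = n * float((interaction3**2).sum())

    ss_within = float((sumsq - sums**2 / n).sum())
    ss_total = float(((y - grand) ** 2).sum())
    return AnovaDecomposition(
        ss=ss,
        df={e: 1 for e in EFFECTS},
        ss_error=ss_within,
        df_error=n_total - 8,
        ss_total=ss_total,
    )


def omega_squared(decomp: AnovaDecomposition, effect: str) -> float:
    """Effect size of one driver:
    ``(SS_effect - df_effect * MS_error) / (MS_error + SS_tot)``.

    May be slightly negative when the effect SS falls below its error
    expectation; reported as computed, not clamped.  Raises
    ``DegenerateDataError`` when all responses are identical.
    """
    if effect not in decomp.ss:
        raise KeyError(f"unknown effect {effect!r}; expected one of {EFFECTS}")
    denom = decomp.ms_error + decomp.ss_total
    if denom == 0:
        raise DegenerateDataError("all responses identical; omega-squared undefined")
    return (decomp.ss[effect] - decomp.df[effect] * decomp.ms_error) / denom


def _reduced_mask(results: pd.DataFrame, driver: str) -> pd.Series:
    """Rows of the reduced model omitting ``driver`` (other toggles on)."""
    col = _FACTOR_COLUMNS[driver]
    others = [c for c in _FACTOR_COLUMNS.values() if c != col]
    mask = ~results[col]
    for other in others:
        mask &= results[other]
    return mask


def _full_mask(results: pd.DataFrame) -> pd.Series:
    return results["harvest"] & results["fire_climate"] & results["stand_climate"]


def _percent_difference(full_mean: float, reduced_mean: float) -> float:
    if reduced_mean == 0:
        return np.nan
    return 100.0 * (full_mean - reduced_mean) / reduced_mean


def delta_prod(
    results: pd.DataFrame, driver: str, response: str = "total_productivity"
) -> pd.DataFrame:
    """Percentage difference in productivity between full and reduced model.

    The full model includes all drivers; the reduced model omits ``driver``
    (harvest off, or fire/stand parameters held at baseline calibration)
    while keeping the others on.  Replicate means are compared per
    scenario and timestep; a zero reduced-model mean yields NaN with the
    ``undefined`` flag set.
    """
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {DRIVERS}")
    full = results[_full_mask(results)]
    reduced = results[_reduced_mask(results, driver)]
    rows = []
    group_cols = ["scenario", "year"]
    fm = full.groupby(group_cols)[response].mean()
    rm = reduced.groupby(group_cols)[response].mean()
    for key in fm.index:
        value = _percent_difference(float(fm[key]), float(rm[key]))
        rows.append(
            {
                "scenario": key[0],
                "year": key[1],
                "driver": driver,
                "delta_prod": value,
                "undefined": bool(np.isnan(value)),
            }
        )
    return pd.DataFrame(rows)


def delta_biomass(results: pd.DataFrame, driver: str, species: str) -> pd.DataFrame:
    """Delta-B: percentage difference in one species' landscape-mean AGB
    between the full and the reduced model (same contract as delta_prod)."""
    col = f"agb_{species}"
    if col not in results.columns:
        raise KeyError(f"no AGB column for species {species!r}")
    out = delta_prod(results, driver, response=col)
    out = out.rename(columns={"delta_prod": "delta_b"})
    out.insert(3, "species", species)
    return out


def sensitivity_table(
    results: pd.DataFrame, response: str = "total_productivity"
) -> pd.DataFrame:
    """Omega-squared and Delta-Prod per scenario, timestep and driver.

    ANOVA is computed separately per scenario and timestep; timesteps whose
    responses are all identical (typically the shared initial snapshot) are
    skipped.
    """
    rows = []
    for (scenario, year), group in results.groupby(["scenario", "year"]):
        try:
            decomp = compute_anova(group, response=response)
            omegas = {d: omega_squared(decomp, d) for d in DRIVERS}
        except (DegenerateDataError, ValueError):
            continue
        for driver in DRIVERS:
            rows.append(
                {
                    "scenario": scenario,
                    "year": year,
                    "driver": driver,
                    "omega2": omegas[driver],
                }
            )
    omega_df = pd.DataFrame(rows, columns=["scenario", "year", "driver", "omega2"])
    deltas = pd.concat(
        [delta_prod(results, d, response=response) for d in DRIVERS],
        ignore_index=True,
    ).drop(columns=["undefined"])
    return omega_df.merge(deltas, on=["scenario", "year", "driver"], how="left")
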