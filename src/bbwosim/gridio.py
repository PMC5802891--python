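"""Raster and tabular I/O.

Per-cell scalar layers are written as ESRI ASCII grids (a plain-text,
dependency-free single-band format readable by every GIS); the full cohort
state goes to a delimited table (cell_id, species, age, biomass).  Floats
are printed with 17 significant digits so write/read round-trips are
bit-exact.  A run manifest (YAML) records the configuration hash, seeds,
scenario, toggles and every file written, which is sufficient to reproduce
a run.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import Config, config_to_dict
from .core import GridSpec, LandscapeState, NEVER_BURNED

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_layers",
    "read_layers",
    "RunManifest",
]

_NODATA = -9999


def write_ascii_grid(
    path, values: np.ndarray, cell_size: float, xll: float = 0.0, yll: float = 0.0
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = top/north)."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xll}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {_NODATA}\n"
    )
    if np.issubdtype(arr.dtype, np.integer):
        fmt = "%d"
    else:
        fmt = "%.17g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:], ndmin=2)
    if arr.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"{path}: shape mismatch against header")
    return arr, meta


_LAYER_FILES = {
    "stand_age": "stand_age.asc",
    "time_since_fire": "time_since_fire.asc",
    "conifer_fraction": "conifer_fraction.asc",
    "pre_fire_age": "pre_fire_age.asc",
    "pre_fire_conifer": "pre_fire_conifer.asc",
    "landtype": "landtype.asc",
    "fire_region": "fire_region.asc",
    "management_area": "management_area.asc",
    "land_tenure": "land_tenure.asc",
}


def write_layers(state: LandscapeState, out_dir, cfg: Config | None = None) -> dict:
    """Write all per-cell layers plus the cohort table; returns the registry.

    The registry maps layer names to file paths; ``meta.yaml`` stores grid
    geometry, the species list and the calendar year, so ``read_layers``
    can rebuild an identical state.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shape = (state.grid.n_rows, state.grid.n_cols)
    cs = state.grid.cell_size_m
    registry = {}
    traits = cfg.species if cfg is not None else None

    def _write(name, arr):
        path = out / _LAYER_FILES[name]
        write_ascii_grid(path, arr.reshape(shape), cs)
        registry[name] = str(path)

    _write("stand_age", state.stand_age_map())
    _write("time_since_fire", state.time_since_fire)
    if traits is not None:
        _write("conifer_fraction", state.conifer_fraction_map(traits))
    _write("pre_fire_age", state.pre_fire_age)
    _write("pre_fire_conifer", state.pre_fire_conifer)
    _write("landtype", state.landtype)
    _write("fire_region", state.fire_region)
    _write("management_area", state.management_area)
    _write("land_tenure", state.land_tenure)

    cohorts = out / "cohorts.csv"
    state.to_cohort_table().to_csv(cohorts, index=False, float_format="%.17g")
    registry["cohorts"] = str(cohorts)

    meta = {
        "grid": asdict(state.grid),
        "species": list(state.species),
        "year": int(state.year),
        "n_age_classes": int(state.n_age_classes),
    }
    meta_path = out / "meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    registry["meta"] = str(meta_path)
    return registry


def read_layers(in_dir) -> LandscapeState:
    """Rebuild a ``LandscapeState`` written by ``write_layers``."""
    src = Path(in_dir)
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    grid = GridSpec(**meta["grid"])
    state = LandscapeState(
        grid,
        species=meta["species"],
        max_longevity=(meta["n_age_classes"] - 1) * grid.timestep,
        year=meta["year"],
    )

    def _read(name, dtype):
        arr, _ = read_ascii_grid(src / _LAYER_FILES[name])
        return arr.ravel().astype(dtype)

    state.time_since_fire = _read("time_since_fire", np.int32)
    state.pre_fire_age = _read("pre_fire_age", np.int32)
    state.pre_fire_conifer = _read("pre_fire_conifer", np.float64)
    state.landtype = _read("landtype", np.int16)
    state.fire_region = _read("fire_region", np.int16)
    state.management_area = _read("management_area", np.int16)
    state.land_tenure = _read("land_tenure", np.int8)
    state.load_cohort_table(
        pd.read_csv(src / "cohorts.csv", float_precision="round_trip")
    )
    return state


@dataclass
class RunManifest:
    """Reproducibility record for one simulation run."""

    config_hash: str
    seed: int
    scenario: str
    toggles: dict
    version: str
    files: dict = field(default_factory=dict)

    @staticmethod
    def config_digest(cfg: Config) -> str:
        blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
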