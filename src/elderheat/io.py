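"""Readers and writers for the pipeline's on-disk formats.

Rasters travel as ESRI ASCII grids (plain text, one 2-D layer per file;
nodata cells are mapped to an explicit mask, never to zero) and daily
temperature stacks as classic NetCDF via xarray. Country/unit tables are
CSV. All writers use the cell-center, north-to-south registration of
:mod:`elderheat.grids`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .containers import CountryAgeProjection, DailyTemperatureEpoch
from .grids import GridGeometry

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_temperature_netcdf",
    "read_temperature_netcdf",
    "write_country_table",
    "read_country_table",
    "load_yaml_config",
    "write_manifest",
]

NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, geometry: GridGeometry,
                     nodata: float = NODATA) -> Path:
    """Write one 2-D layer as an ESRI ASCII grid (rows north to south)."""
    values = np.ma.asarray(values, dtype=np.float64)
    if values.shape != geometry.shape:
        raise ValueError("layer shape does not match geometry")
    path = Path(path)
    filled = values.filled(nodata) if np.ma.isMaskedArray(values) else np.asarray(values)
    yll = geometry.y_origin - geometry.nrows * geometry.cell_size
    header = (
        f"ncols {geometry.ncols}\n"
        f"nrows {geometry.nrows}\n"
        f"xllcorner {geometry.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in filled:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_ascii_grid(path) -> tuple[np.ma.MaskedArray, GridGeometry]:
    """Read an ESRI ASCII grid; nodata cells come back masked, never 0."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise ValueError(
            f"{path}: ambiguous georeferencing, missing "
            f"{sorted(required - set(header))}"
        )
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.loadtxt(lines[n_header:], dtype=np.float64).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    masked = np.ma.masked_equal(data, nodata) if nodata is not None else np.ma.asarray(data)
    geometry = GridGeometry(
        nrows=nrows,
        ncols=ncols,
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
    )
    return masked, geometry


def write_temperature_netcdf(path, epoch: DailyTemperatureEpoch) -> Path:
    """Classic NetCDF with CF-style ``tas``/``tasmax`` daily variables."""
    path = Path(path)
    epoch.to_xarray().to_netcdf(path, engine="scipy")
    return path


def read_temperature_netcdf(path, *, tmean_var: str = "tas",
                            tmax_var: str = "tasmax") -> DailyTemperatureEpoch:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        return DailyTemperatureEpoch.from_xarray(
            ds.load(), tmean_var=tmean_var, tmax_var=tmax_var
        )


def write_country_table(path, projection: CountryAgeProjection) -> Path:
    path = Path(path)
    projection.table.to_csv(path, index=False)
    return path


def read_country_table(path) -> CountryAgeProjection:
    return CountryAgeProjection(pd.read_csv(Path(path)))


def load_yaml_config(path) -> dict:
    with open(Path(path)) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out


def write_manifest(path, entries: dict) -> Path:
    """JSON manifest of emitted artifacts, config hash and versions."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
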