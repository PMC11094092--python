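"""In-memory containers shared across the pipeline.

All temperatures are degrees Celsius, all population values are persons.
Grids follow the cell-center, north-to-south convention of
:mod:`elderheat.grids`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import NO_COUNTRY, GridGeometry

__all__ = [
    "BASE_YEAR_SCENARIO",
    "PopulationGrid",
    "CountryAgeProjection",
    "AgeFractionSurface",
    "DailyTemperatureEpoch",
    "HeatMetricSurface",
    "validate_country_table",
]

#: Reserved scenario label for the observed base-year population.
BASE_YEAR_SCENARIO = "base"


@dataclass
class PopulationGrid:
    """Per-cell, per-age-stratum person counts with a country-ID layer.

    ``counts`` has shape (n_strata, nrows, ncols). ``elderly`` marks which
    strata fall on or above the old-age cutoff (69 by default); the strata
    must partition the population, so every stratum is either below or at/
    above the cutoff with no overlap.
    """

    counts: np.ndarray
    strata: tuple[str, ...]
    elderly: tuple[bool, ...]
    geometry: GridGeometry
    country_id: np.ndarray
    year: int = 2020
    scenario: str = BASE_YEAR_SCENARIO

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.country_id = np.asarray(self.country_id)
        self.strata = tuple(self.strata)
        self.elderly = tuple(bool(b) for b in self.elderly)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.strata):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strata)} strata on grid {self.geometry.shape}"
            )
        if self.counts.shape[1:] != self.geometry.shape:
            raise ValueError("counts grid does not match geometry")
        if self.country_id.shape != self.geometry.shape:
            raise ValueError("country_id grid does not match geometry")
        if len(self.elderly) != len(self.strata):
            raise ValueError("elderly flags must match strata")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("population counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")
        populated = self.total() > 0
        if np.any(populated & (self.country_id == NO_COUNTRY)):
            raise ValueError("country_id undefined on populated cells")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def total(self) -> np.ndarray:
        """Total persons per cell across all age strata."""
        return self.counts.sum(axis=0)

    def elderly_count(self) -> np.ndarray:
        """Persons in 69+ strata per cell."""
        mask = np.asarray(self.elderly, dtype=bool)
        return self.counts[mask].sum(axis=0)

    def young_count(self) -> np.ndarray:
        mask = ~np.asarray(self.elderly, dtype=bool)
        return self.counts[mask].sum(axis=0)

    def countries(self) -> np.ndarray:
        """Sorted unique country ids present on the grid (excluding none)."""
        ids = np.unique(self.country_id)
        return ids[ids != NO_COUNTRY]

    def with_counts(self, counts: np.ndarray, year: int, scenario: str) -> "PopulationGrid":
        return replace(self, counts=counts, year=year, scenario=scenario)


COUNTRY_TABLE_COLUMNS = ["country", "age_stratum", "scenario", "year", "persons"]


def validate_country_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a country-level age-stratified projection table.

    One row per (country, age_stratum, scenario, year); persons finite >= 0.
    """
    missing = [c for c in COUNTRY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"country table missing columns: {missing}")
    key = ["country", "age_stratum", "scenario", "year"]
    if table.duplicated(subset=key).any():
        dups = table[table.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate country-table rows:\n{dups[key]}")
    persons = table["persons"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(persons)) or np.any(persons < 0):
        raise ValueError("country table persons must be finite and non-negative")
    return table


@dataclass
class CountryAgeProjection:
    """Country-level age-stratified population projections (long table)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = validate_country_table(pd.DataFrame(self.table))

    def lookup(self, country: int, stratum: str, scenario: str) -> float:
        sel = self.table[
            (self.table["country"] == country)
            & (self.table["age_stratum"] == stratum)
            & (self.table["scenario"] == scenario)
        ]
        if sel.empty:
            raise KeyError(
                f"no projection row for country {country!r}, stratum "
                f"{stratum!r}, scenario {scenario!r}"
            )
        return float(sel["persons"].iloc[0])


@dataclass
class AgeFractionSurface:
    """Per-cell share of population aged 69+ (``a_plus``) and below.

    Cells with zero total population carry NaN (undefined), never 0.
    """

    a_plus: np.ndarray
    geometry: GridGeometry
    scenario: str
    year: int

    def __post_init__(self) -> None:
        self.a_plus = np.asarray(self.a_plus, dtype=np.float64)
        if self.a_plus.shape != self.geometry.shape:
            raise ValueError("a_plus does not match geometry")
        defined = np.isfinite(self.a_plus)
        vals = self.a_plus[defined]
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("a_plus must lie in [0, 1] where defined")

    @property
    def a_minus(self) -> np.ndarray:
        return 1.0 - self.a_plus

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.a_plus)


@dataclass
class DailyTemperatureEpoch:
    """Daily mean and maximum temperature stacks for one model/scenario epoch.

    ``tmean``/``tmax`` have shape (n_days, nrows, ncols) with
    ``n_days = years * days_per_year`` (idealized calendar; ingestion of real
    data normalizes calendars before constructing an epoch).
    """

    tmean: np.ndarray
    tmax: np.ndarray
    geometry: GridGeometry
    model: str
    scenario: str
    epoch: str
    days_per_year: int = 365

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, dtype=np.float64)
        self.tmax = np.asarray(self.tmax, dtype=np.float64)
        if self.tmean.shape != self.tmax.shape or self.tmean.ndim != 3:
            raise ValueError("tmean and tmax must be equal-shape 3-D stacks")
        if self.tmean.shape[1:] != self.geometry.shape:
            raise ValueError("temperature stack does not match geometry")
        if self.tmean.shape[0] == 0:
            raise ValueError("temperature epoch is empty")
        if self.tmean.shape[0] % self.days_per_year:
            raise ValueError(
                f"day count {self.tmean.shape[0]} is not a whole number of "
                f"{self.days_per_year}-day years"
            )
        if not (np.all(np.isfinite(self.tmean)) and np.all(np.isfinite(self.tmax))):
            raise ValueError("temperatures must be finite")
        if np.any(self.tmax < self.tmean - 1e-9):
            raise ValueError("daily maximum below daily mean")

    @property
    def n_days(self) -> int:
        return self.tmean.shape[0]

    @property
    def years(self) -> int:
        return self.n_days // self.days_per_year

    def by_year(self, which: str = "tmean") -> np.ndarray:
        """Reshape a stack to (years, days_per_year, nrows, ncols)."""
        arr = self.tmean if which == "tmean" else self.tmax
        return arr.reshape(self.years, self.days_per_year, *self.geometry.shape)

    def to_xarray(self) -> xr.Dataset:
        lon, lat = self.geometry.cell_centers()
        ds = xr.Dataset(
            {
                "tas": (("day", "lat", "lon"), self.tmean),
                "tasmax": (("day", "lat", "lon"), self.tmax),
            },
            coords={
                "day": np.arange(self.n_days),
                "lat": lat[:, 0],
                "lon": lon[0, :],
            },
            attrs={
                "model": self.model,
                "scenario": self.scenario,
                "epoch": self.epoch,
                "days_per_year": self.days_per_year,
                "units": "degC",
                "registration": "cell-center, rows north to south",
            },
        )
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset, *, tmean_var: str = "tas",
                    tmax_var: str = "tasmax") -> "DailyTemperatureEpoch":
        lat = np.asarray(ds["lat"])
        lon = np.asarray(ds["lon"])
        cell = float(abs(lat[1] - lat[0])) if lat.size > 1 else (
            float(abs(lon[1] - lon[0])) if lon.size > 1 else 1.0
        )
        geom = GridGeometry(
            nrows=lat.size, ncols=lon.size, cell_size=cell,
            x_origin=float(lon[0]) - cell / 2, y_origin=float(lat[0]) + cell / 2,
        )
        return cls(
            tmean=np.asarray(ds[tmean_var]),
            tmax=np.asarray(ds[tmax_var]),
            geometry=geom,
            model=str(ds.attrs.get("model", "unknown")),
            scenario=str(ds.attrs.get("scenario", "unknown")),
            epoch=str(ds.attrs.get("epoch", "unknown")),
            days_per_year=int(ds.attrs.get("days_per_year", 365)),
        )


@dataclass
class HeatMetricSurface:
    """A per-cell heat metric (CDD, TMAX95 or hot-day frequency).

    ``values`` units depend on the metric: degC*day/yr for ``cdd`` (epoch
    mean of annual cooling degree days), degC for ``tmax95``, days/yr for
    ``hd``. ``aux`` carries metric-specific extras (per-year CDD series, raw
    epoch hot-day counts).
    """

    values: np.ndarray
    metric: str
    geometry: GridGeometry
    scenario: str
    epoch: str
    model: str = "ensemble-median"
    threshold: float | None = None
    aux: dict = field(default_factory=dict)

    VALID_METRICS = ("cdd", "tmax95", "hd")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.metric not in self.VALID_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.values.shape != self.geometry.shape:
            raise ValueError("metric surface does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")
        if self.metric in ("cdd", "hd") and np.any(self.values < -1e-12):
            raise ValueError(f"{self.metric} must be non-negative")
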