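"""Synthetic inputs with known ground truth for the exposure pipeline.

Emulates the five input families the real analysis consumes — base-year
age-stratified population counts on a fine grid, gridded total-population
projections per scenario, country-level age-stratified projections per
scenario, per-model daily temperature stacks for a historical and a future
epoch, and a country-ID raster — with controllable ground truth so that
every downstream stage can be verified without any external download.

Design of the demographic truth
-------------------------------
Countries are axis-aligned blocks of climate cells. The hidden year-2050
truth grid is built with *within-country spatially homogeneous* growth per
age stratum: ``truth[a, g] = r[a, c(g)] * base[a, g]``. Country tables are
the exact country sums of that truth, and gridded total projections are its
exact age sums, so the two-level constrained growth-factor procedure can
recover the truth. Exact recovery additionally requires the base-year age
*composition* to be constant within each country (otherwise the total
growth factor varies cell-to-cell inside a country and the country-level
age adjustment cannot undo it); the generator therefore draws the 69+ share
as a smooth gradient across countries, constant within each. An optional
perturbation injects within-country heterogeneity into the elderly growth
rate — a known, tunable violation of the homogeneity assumption used to
benchmark downscaling error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    BASE_YEAR_SCENARIO,
    CountryAgeProjection,
    DailyTemperatureEpoch,
    PopulationGrid,
)
from .grids import GridGeometry

import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticPopulation",
    "generate_temperature_epoch",
    "generate_population_inputs",
    "country_layout",
]

#: Scenario label for the historical epoch (warming offset 0 by definition).
HISTORICAL = "historical"


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world.

    The defaults emulate the study conditions at desk scale: a 10 x 10
    climate grid (0.25-degree-like cells), a 2x finer population grid,
    4 countries, two age strata split at 69, 20-year epochs of 365-day
    years, a seasonal cycle of +/-8 degC, a 10 degC diurnal range, and
    end-of-pipeline warming offsets spanning the scenario range.
    """

    nrows: int = 10
    ncols: int = 10
    refinement: int = 2
    n_countries: int = 4
    strata: tuple[str, ...] = ("lt69", "ge69")
    elderly: tuple[bool, ...] = (False, True)
    epoch_years: int = 20
    days_per_year: int = 365
    warming: dict = field(
        default_factory=lambda: {
            HISTORICAL: 0.0,
            "ssp126": 1.0,
            "ssp245": 1.5,
            "ssp370": 2.0,
            "ssp585": 3.0,
        }
    )
    seasonal_amplitude: float = 8.0
    diurnal_range: float = 10.0
    noise_sd: float = 1.5
    baseline_south: float = 28.0
    baseline_north: float = 8.0
    zonal_amplitude: float = 0.5
    seasonal_phase: float = 0.0
    elderly_growth: tuple[float, float] = (2.0, 3.5)
    young_growth: tuple[float, float] = (0.9, 1.5)
    seed: int = 0
    base_year: int = 2020
    target_year: int = 2050
    cell_size: float = 0.25

    def __post_init__(self) -> None:
        if self.refinement != int(self.refinement) or self.refinement < 1:
            raise ValueError("refinement factor must be an integer >= 1")
        if self.epoch_years < 1:
            raise ValueError("epoch length must be >= 1 year")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if len(self.strata) != len(self.elderly) or not any(self.elderly):
            raise ValueError("strata/elderly flags inconsistent or no 69+ stratum")
        if HISTORICAL not in self.warming:
            raise ValueError("warming offsets must include the historical epoch")
        for s, off in self.warming.items():
            if not np.isfinite(off):
                raise ValueError(f"warming offset for {s!r} must be finite")

    @property
    def scenarios(self) -> tuple[str, ...]:
        """Future scenarios (everything except the historical epoch)."""
        return tuple(s for s in self.warming if s != HISTORICAL)

    @property
    def climate_geometry(self) -> GridGeometry:
        return GridGeometry(self.nrows, self.ncols, cell_size=self.cell_size)

    @property
    def population_geometry(self) -> GridGeometry:
        return self.climate_geometry.refine(self.refinement)

    def require_scenario(self, scenario: str) -> float:
        if scenario not in self.warming:
            raise KeyError(
                f"unknown scenario {scenario!r}; configured: "
                f"{sorted(self.warming)}"
            )
        return float(self.warming[scenario])


def _rng(config: SyntheticConfig, *stream: object) -> np.random.Generator:
    """Independent, reproducible stream keyed on the config seed.

    Stream labels are hashed with CRC32 (stable across processes, unlike
    Python's salted ``hash``) so reruns are bit-identical.
    """
    ss = np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=tuple(zlib.crc32(str(s).encode()) for s in stream),
    )
    return np.random.default_rng(ss)


def country_layout(config: SyntheticConfig) -> np.ndarray:
    """Country-ID raster on the climate grid: axis-aligned column strips.

    Countries are contiguous vertical strips of climate columns, id 0..n-1
    west to east; widths as equal as the division allows.
    """
    if config.n_countries < 1 or config.n_countries > config.ncols:
        raise ValueError("n_countries must be in [1, ncols]")
    edges = np.linspace(0, config.ncols, config.n_countries + 1).astype(int)
    row = np.empty(config.ncols, dtype=np.int64)
    for cid in range(config.n_countries):
        row[edges[cid]: edges[cid + 1]] = cid
    return np.broadcast_to(row, (config.nrows, config.ncols)).copy()


def _baseline_field(config: SyntheticConfig) -> np.ndarray:
    """Cell climatological mean: north-south gradient, warm toward high rows."""
    rows = np.arange(config.nrows, dtype=np.float64)
    frac = rows / max(config.nrows - 1, 1)
    lat_profile = config.baseline_north + frac * (
        config.baseline_south - config.baseline_north
    )
    base = np.broadcast_to(lat_profile[:, None], (config.nrows, config.ncols)).copy()
    # fixed east-west texture so cells within a latitude band are not identical
    cols = np.arange(config.ncols, dtype=np.float64)
    base += config.zonal_amplitude * np.sin(2 * np.pi * cols / max(config.ncols, 1))
    return base


def generate_temperature_epoch(
    config: SyntheticConfig, scenario: str, model_index: int = 0
) -> DailyTemperatureEpoch:
    """Daily mean/max temperature stack for one scenario and climate model.

    Daily mean = cell baseline + seasonal sinusoid + scenario warming offset
    + seeded Gaussian noise; daily max = daily mean + diurnal range / 2.
    The noise stream is keyed on (seed, scenario, model_index) so models are
    exchangeable draws around the same climatology and reruns are
    bit-identical.
    """
    offset = config.require_scenario(scenario)
    n_days = config.epoch_years * config.days_per_year
    day = np.arange(n_days, dtype=np.float64)
    season = config.seasonal_amplitude * np.sin(
        2 * np.pi * day / config.days_per_year + config.seasonal_phase
    )
    base = _baseline_field(config)
    tmean = base[None, :, :] + season[:, None, None] + offset
    if config.noise_sd > 0:
        rng = _rng(config, "temperature", scenario, model_index)
        tmean = tmean + rng.normal(0.0, config.noise_sd, size=tmean.shape)
    tmax = tmean + config.diurnal_range / 2.0
    return DailyTemperatureEpoch(
        tmean=tmean,
        tmax=tmax,
        geometry=config.climate_geometry,
        model=f"model{model_index:02d}",
        scenario=scenario,
        epoch=HISTORICAL if scenario == HISTORICAL else str(config.target_year),
        days_per_year=config.days_per_year,
    )


@dataclass
class SyntheticPopulation:
    """Bundle of demographic inputs plus the hidden truth (test-only).

    ``truth`` is the ground-truth future grid per scenario. It exists so
    tests can assert recovery; the downscaling pipeline must never read it.
    """

    base: PopulationGrid
    total_projection: dict
    country_projection: CountryAgeProjection
    truth: dict
    truth_age_fraction: dict
    country_id_fine: np.ndarray


def _perturbation_pattern(config: SyntheticConfig) -> np.ndarray:
    """Deterministic within-country pattern in [-1, 1], zero-mean-ish.

    A fixed horizontal sawtooth across each country's fine columns; it does
    not depend on the seed so perturbation magnitudes are comparable across
    seeds.
    """
    geom = config.population_geometry
    cid = np.kron(country_layout(config), np.ones((config.refinement, config.refinement), dtype=np.int64))
    pat = np.zeros(geom.shape, dtype=np.float64)
    for c in np.unique(cid):
        mask = cid == c
        cols = np.where(mask.any(axis=0))[0]
        ramp = np.linspace(-1.0, 1.0, cols.size)
        for j, col in enumerate(cols):
            pat[:, col][mask[:, col]] = ramp[j]
    return pat


def generate_population_inputs(
    config: SyntheticConfig, perturbation: float = 0.0
) -> SyntheticPopulation:
    """Base-year grid, projections, country tables and hidden truth.

    ``perturbation`` m > 0 multiplies the elderly growth rate cell-wise by
    ``(1 + m * p_g)`` with a fixed zero-mean within-country pattern ``p_g``,
    breaking the within-country homogeneity the downscaling assumes while
    keeping all emitted inputs exactly self-consistent (country tables and
    gridded totals remain exact sums of the perturbed truth).
    """
    if perturbation < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    geom = config.population_geometry
    f = config.refinement
    cid_climate = country_layout(config)
    cid_fine = np.kron(cid_climate, np.ones((f, f), dtype=np.int64))

    rng = _rng(config, "population")

    # Base-year totals: smooth gradient times a lognormal texture.
    rows = np.arange(geom.nrows, dtype=np.float64)[:, None]
    cols = np.arange(geom.ncols, dtype=np.float64)[None, :]
    density = 200.0 + 800.0 * (
        0.5 + 0.5 * np.sin(2 * np.pi * rows / geom.nrows) * np.cos(2 * np.pi * cols / geom.ncols)
    )
    texture = rng.lognormal(mean=0.0, sigma=0.4, size=geom.shape)
    total = density * texture

    # 69+ share: smooth gradient ACROSS countries, constant within each
    # (required for exact recovery; see module docstring).
    n_c = config.n_countries
    shares = 0.05 + 0.15 * np.arange(n_c) / max(n_c - 1, 1)
    share_map = shares[cid_fine]

    elderly_idx = [i for i, e in enumerate(config.elderly) if e]
    young_idx = [i for i, e in enumerate(config.elderly) if not e]
    counts = np.zeros((len(config.strata), *geom.shape))
    # split the elderly/young masses evenly across their strata
    for i in elderly_idx:
        counts[i] = total * share_map / len(elderly_idx)
    for i in young_idx:
        counts[i] = total * (1.0 - share_map) / len(young_idx)

    base = PopulationGrid(
        counts=counts,
        strata=config.strata,
        elderly=config.elderly,
        geometry=geom,
        country_id=cid_fine,
        year=config.base_year,
        scenario=BASE_YEAR_SCENARIO,
    )

    # Per-country, per-stratum, per-scenario growth rates: elderly
    # populations roughly double-to-triple by mid-century, younger strata
    # change more modestly, later (warmer) scenarios grow slightly more.
    pat = _perturbation_pattern(config) if perturbation > 0 else None
    truth: dict = {}
    truth_fraction: dict = {}
    total_projection: dict = {}
    rows_out = []
    for k, scen in enumerate(config.scenarios):
        g_rng = _rng(config, "growth", scen)
        growth = np.empty((len(config.strata), n_c))
        for i in range(len(config.strata)):
            lo, hi = config.elderly_growth if config.elderly[i] else config.young_growth
            growth[i] = g_rng.uniform(lo, hi, size=n_c) * (1.0 + 0.05 * k)
        rate_map = growth[:, cid_fine]  # (stratum, rows, cols)
        if pat is not None:
            for i in elderly_idx:
                rate_map[i] = rate_map[i] * (1.0 + perturbation * pat)
        t = rate_map * counts
        truth[scen] = base.with_counts(t, year=config.target_year, scenario=scen)
        tot = t.sum(axis=0)
        total_projection[scen] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, t[elderly_idx].sum(axis=0) / tot, np.nan)
        truth_fraction[scen] = frac
        for c in range(n_c):
            mask = cid_fine == c
            for i, stratum in enumerate(config.strata):
                rows_out.append(
                    {
                        "country": c,
                        "age_stratum": stratum,
                        "scenario": scen,
                        "year": config.target_year,
                        "persons": float(t[i][mask].sum()),
                    }
                )
    country_projection = CountryAgeProjection(pd.DataFrame(rows_out))
    return SyntheticPopulation(
        base=base,
        total_projection=total_projection,
        country_projection=country_projection,
        truth=truth,
        truth_age_fraction=truth_fraction,
        country_id_fine=cid_fine,
    )
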