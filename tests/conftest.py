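import numpy as np
import pytest

from elderheat import (
    DailyTemperatureEpoch,
    GridGeometry,
    PopulationGrid,
    SyntheticConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale synthetic world used across tests."""
    return SyntheticConfig(seed=7)


@pytest.fixture
def quiet_config():
    """Noise-free, season-free, flat-baseline world for exact-value checks."""
    return SyntheticConfig(
        seed=7,
        noise_sd=0.0,
        seasonal_amplitude=0.0,
        zonal_amplitude=0.0,
        baseline_north=20.0,
        baseline_south=20.0,
        warming={"historical": 0.0, "plus3": 3.0},
    )


def random_epoch(rng, nrows=5, ncols=4, years=3, days_per_year=10,
                 scenario="historical", model="m0"):
    """Random but valid temperature epoch for oracle comparisons."""
    geom = GridGeometry(nrows, ncols)
    tmean = rng.normal(22.0, 6.0, size=(years * days_per_year, nrows, ncols))
    tmax = tmean + rng.uniform(0.0, 12.0, size=tmean.shape)
    return DailyTemperatureEpoch(
        tmean=tmean, tmax=tmax, geometry=geom, model=model,
        scenario=scenario, epoch="test", days_per_year=days_per_year,
    )


def random_population(rng, nrows=6, ncols=6, n_countries=3, zero_cells=0):
    """Random two-stratum population grid with column-strip countries."""
    geom = GridGeometry(nrows, ncols)
    counts = rng.uniform(0.0, 100.0, size=(2, nrows, ncols))
    if zero_cells:
        flat = rng.choice(nrows * ncols, size=zero_cells, replace=False)
        for idx in flat:
            counts[:, idx // ncols, idx % ncols] = 0.0
    edges = np.linspace(0, ncols, n_countries + 1).astype(int)
    country = np.zeros((nrows, ncols), dtype=np.int64)
    for c in range(n_countries):
        country[:, edges[c]:edges[c + 1]] = c
    return PopulationGrid(
        counts=counts, strata=("lt69", "ge69"), elderly=(False, True),
        geometry=geom, country_id=country,
    )
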