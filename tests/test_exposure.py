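"""Exposure surfaces, regional aggregation, exceedance curves."""

import numpy as np
import pytest

from elderheat import (
    GridGeometry,
    HeatMetricSurface,
    PopulationGrid,
    age_fractions,
    aggregate_regions,
    align_population_to_climate_grid,
    derived_cdd_threshold,
    exceedance_curve,
    exposure_surface,
    threshold_population_change,
)
from conftest import random_population


def metric_from(values, metric="cdd", scenario="s"):
    values = np.asarray(values, dtype=np.float64)
    return HeatMetricSurface(
        values=values, metric=metric, geometry=GridGeometry(*values.shape),
        scenario=scenario, epoch="e", model="m",
    )


def uniform_population(nrows, ncols, per_stratum=10.0):
    return PopulationGrid(
        counts=np.full((2, nrows, ncols), per_stratum),
        strata=("lt69", "ge69"), elderly=(False, True),
        geometry=GridGeometry(nrows, ncols),
        country_id=np.zeros((nrows, ncols), dtype=np.int64),
    )


class TestAlignment:
    def test_refinement_one_is_identity(self, rng):
        pop = random_population(rng)
        out = align_population_to_climate_grid(pop, pop.geometry)
        assert out is pop

    def test_block_sum_of_uniform_fine_cells(self):
        pop = uniform_population(2, 2, per_stratum=5.0)  # 10 persons/cell
        coarse = align_population_to_climate_grid(pop, GridGeometry(1, 1, cell_size=2.0))
        assert coarse.total()[0, 0] == pytest.approx(40.0)

    def test_population_mass_is_conserved(self, rng):
        pop = random_population(rng, nrows=8, ncols=8, n_countries=4)
        coarse = align_population_to_climate_grid(pop, GridGeometry(2, 2, cell_size=4.0))
        assert coarse.counts.sum() == pytest.approx(pop.counts.sum(), rel=1e-12)
        np.testing.assert_allclose(
            coarse.counts.sum(axis=(1, 2)), pop.counts.sum(axis=(1, 2)),
            rtol=1e-12,
        )

    def test_country_is_population_weighted_mode(self):
        pop = uniform_population(2, 2)
        pop.counts[:, 0, 0] = 100.0  # dominant cell
        cid = np.array([[3, 1], [1, 1]], dtype=np.int64)
        pop = PopulationGrid(
            counts=pop.counts, strata=pop.strata, elderly=pop.elderly,
            geometry=pop.geometry, country_id=cid,
        )
        coarse = align_population_to_climate_grid(pop, GridGeometry(1, 1, cell_size=2.0))
        assert coarse.country_id[0, 0] == 3

    def test_non_integer_ratio_instructs_resampling(self, rng):
        pop = random_population(rng, nrows=6, ncols=6)
        with pytest.raises(ValueError, match="resampl"):
            align_population_to_climate_grid(
                pop, GridGeometry(4, 4, cell_size=1.5)
            )


class TestExposureSurface:
    def test_product_arithmetic(self):
        pop = uniform_population(1, 1, per_stratum=500.0)  # N = 1000
        frac = age_fractions(pop)  # A+ = 0.5
        pop.counts[1, 0, 0] = 100.0
        pop.counts[0, 0, 0] = 900.0
        frac = age_fractions(pop)  # A+ = 0.1
        surf = exposure_surface(metric_from([[500.0]]), pop, frac, "ge69")
        assert surf.values[0, 0] == pytest.approx(0.1 * 1000 * 500)
        assert surf.name == "pdd"

    def test_zero_population_gives_zero_exposure(self):
        pop = uniform_population(2, 2, per_stratum=0.0)
        frac = age_fractions(pop)  # all NaN
        surf = exposure_surface(metric_from(np.full((2, 2), 9.0)), pop, frac)
        np.testing.assert_array_equal(surf.values, 0.0)

    def test_matches_cell_loop_oracle(self, rng):
        pop = random_population(rng, nrows=5, ncols=5)
        frac = age_fractions(pop)
        metric = metric_from(rng.uniform(0, 800, size=(5, 5)))
        surf = exposure_surface(metric, pop, frac, "ge69")
        for i in range(5):
            for j in range(5):
                total = pop.counts[:, i, j].sum()
                share = pop.counts[1, i, j] / total if total > 0 else 0.0
                assert surf.values[i, j] == pytest.approx(
                    share * total * metric.values[i, j], rel=1e-12
                )

    def test_grid_mismatch_rejected(self, rng):
        pop = random_population(rng, nrows=5, ncols=5)
        with pytest.raises(ValueError, match="align"):
            exposure_surface(metric_from(np.zeros((3, 3))), pop, None)

    def test_linearity_in_population(self, rng):
        pop = random_population(rng, nrows=4, ncols=4)
        doubled = PopulationGrid(
            counts=pop.counts * 2, strata=pop.strata, elderly=pop.elderly,
            geometry=pop.geometry, country_id=pop.country_id,
        )
        metric = metric_from(rng.uniform(0, 100, size=(4, 4)))
        s1 = exposure_surface(metric, pop, age_fractions(pop))
        s2 = exposure_surface(metric, doubled, age_fractions(doubled))
        np.testing.assert_allclose(s2.values, 2 * s1.values, rtol=1e-12)


class TestRegionalAggregation:
    def test_single_region_equals_global_sum(self, rng):
        pop = random_population(rng, nrows=4, ncols=4, n_countries=1)
        surf = exposure_surface(
            metric_from(rng.uniform(0, 100, (4, 4))), pop, age_fractions(pop)
        )
        table = aggregate_regions(surf, pop.country_id)
        world = table.loc[table.region == "World", "value"].iloc[0]
        region0 = table.loc[table.region == "0", "value"].iloc[0]
        assert region0 == pytest.approx(world, rel=1e-14)

    def test_partition_additivity(self, rng):
        pop = random_population(rng, nrows=6, ncols=6, n_countries=3)
        surf = exposure_surface(
            metric_from(rng.uniform(0, 100, (6, 6))), pop, age_fractions(pop)
        )
        table = aggregate_regions(surf, pop.country_id)
        regions = table[~table.region.isin(["World", "unassigned"])]
        world = table.loc[table.region == "World", "value"].iloc[0]
        assert regions["value"].sum() == pytest.approx(world, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        pop = random_population(rng, nrows=6, ncols=6, n_countries=3)
        surf = exposure_surface(
            metric_from(rng.uniform(0, 100, (6, 6))), pop, age_fractions(pop)
        )
        table = aggregate_regions(surf, pop.country_id).set_index("region")
        for c in range(3):
            expected = 0.0
            for i in range(6):
                for j in range(6):
                    if pop.country_id[i, j] == c:
                        expected += surf.values[i, j]
            assert table.loc[str(c), "value"] == pytest.approx(expected, rel=1e-12)

    def test_unmapped_exposure_reported_as_unassigned(self, rng, caplog):
        pop = random_population(rng, nrows=4, ncols=4, n_countries=1)
        surf = exposure_surface(
            metric_from(np.full((4, 4), 10.0)), pop, age_fractions(pop)
        )
        region_map = pop.country_id.copy()
        region_map[0, 0] = -1
        with caplog.at_level("WARNING"):
            table = aggregate_regions(surf, region_map)
        assert "unassigned" in set(table.region)
        assert "unmapped" in caplog.text


class TestExceedance:
    def test_extreme_thresholds(self, rng):
        pop = random_population(rng, nrows=5, ncols=5)
        frac = age_fractions(pop)
        metric = metric_from(rng.uniform(10, 20, (5, 5)))
        curve = exceedance_curve(metric, pop, frac, "ge69",
                                 np.array([0.0, 100.0]))
        assert curve.counts[0] == pytest.approx(pop.elderly_count().sum(), rel=1e-12)
        assert curve.counts[1] == 0.0

    def test_matches_brute_force_scan(self, rng):
        pop = random_population(rng, nrows=5, ncols=5)
        frac = age_fractions(pop)
        metric = metric_from(rng.uniform(0, 50, (5, 5)))
        thresholds = np.sort(rng.uniform(0, 50, size=11))
        curve = exceedance_curve(metric, pop, frac, "ge69", thresholds)
        persons = pop.elderly_count()
        for k, x in enumerate(thresholds):
            expected = sum(
                persons[i, j]
                for i in range(5) for j in range(5)
                if metric.values[i, j] >= x
            )
            assert curve.counts[k] == pytest.approx(expected, rel=1e-12)

    def test_curve_is_non_increasing(self, rng):
        pop = random_population(rng)
        metric = metric_from(rng.uniform(0, 50, pop.geometry.shape))
        curve = exceedance_curve(metric, pop, age_fractions(pop), "ge69",
                                 np.linspace(0, 60, 40))
        assert np.all(np.diff(curve.counts) <= 0)

    def test_identical_scenarios_give_zero_change(self, rng):
        pop = random_population(rng)
        metric = metric_from(rng.uniform(0, 50, pop.geometry.shape))
        grid = np.linspace(0, 60, 20)
        c = exceedance_curve(metric, pop, age_fractions(pop), "ge69", grid)
        assert threshold_population_change(c, c, 30.0) == 0.0

    def test_change_antisymmetric_and_counts_crossers(self, rng):
        pop = random_population(rng, nrows=4, ncols=4, n_countries=1)
        frac = age_fractions(pop)
        base_vals = np.full((4, 4), 20.0)
        base_vals[0, :2] = 29.0  # these cells cross under +2 warming
        fut_vals = base_vals + 2.0
        grid = np.array([0.0, 30.0, 60.0])
        base_c = exceedance_curve(metric_from(base_vals), pop, frac, "ge69", grid)
        fut_c = exceedance_curve(metric_from(fut_vals), pop, frac, "ge69", grid)
        crossers = pop.elderly_count()[0, :2].sum()
        assert threshold_population_change(fut_c, base_c, 30.0) == pytest.approx(
            crossers, rel=1e-12
        )
        assert threshold_population_change(base_c, fut_c, 30.0) == pytest.approx(
            -crossers, rel=1e-12
        )


class TestDerivedCddThreshold:
    def test_constant_cdd_over_qualifying_cells(self):
        cdd = metric_from(np.full((3, 3), 777.0))
        tmax = metric_from(np.full((3, 3), 40.0), metric="tmax95")
        assert derived_cdd_threshold(cdd, tmax) == pytest.approx(777.0)

    def test_no_qualifying_cells_is_undefined(self):
        cdd = metric_from(np.full((3, 3), 777.0))
        tmax = metric_from(np.full((3, 3), 30.0), metric="tmax95")
        with pytest.raises(ValueError, match="undefined"):
            derived_cdd_threshold(cdd, tmax)

    def test_matches_masked_mean_oracle(self, rng):
        cdd_vals = rng.uniform(0, 2000, (6, 6))
        tmax_vals = rng.uniform(30, 45, (6, 6))
        got = derived_cdd_threshold(
            metric_from(cdd_vals), metric_from(tmax_vals, metric="tmax95")
        )
        sel = [cdd_vals[i, j] for i in range(6) for j in range(6)
               if tmax_vals[i, j] > 37.5]
        assert got == pytest.approx(np.mean(sel), rel=1e-12)

    def test_population_weighted_variant(self, rng):
        pop = random_population(rng, nrows=4, ncols=4)
        frac = age_fractions(pop)
        cdd_vals = rng.uniform(0, 2000, (4, 4))
        tmax_vals = rng.uniform(36, 42, (4, 4))
        got = derived_cdd_threshold(
            metric_from(cdd_vals), metric_from(tmax_vals, metric="tmax95"),
            pop=pop, fractions=frac, population_weighted=True,
        )
        qualifying = tmax_vals > 37.5
        w = (pop.total() * np.nan_to_num(frac.a_plus))[qualifying]
        expected = np.average(cdd_vals[qualifying], weights=w)
        assert got == pytest.approx(expected, rel=1e-12)
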