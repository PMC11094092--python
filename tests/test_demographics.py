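"""Two-level constrained growth-factor downscaling."""

import numpy as np
import pandas as pd
import pytest

from elderheat import (
    CountryAgeProjection,
    GridGeometry,
    PopulationGrid,
    age_fractions,
    country_age_adjustments,
    downscale,
    generate_population_inputs,
    project_population,
    total_growth_factors,
)
from elderheat.demographics import constraint_residual
from conftest import random_population


def make_table(rows):
    return CountryAgeProjection(
        pd.DataFrame(
            [
                {"country": c, "age_stratum": a, "scenario": s,
                 "year": 2050, "persons": p}
                for c, a, s, p in rows
            ]
        )
    )


def single_cell_grid(lt69=80.0, ge69=20.0):
    return PopulationGrid(
        counts=np.array([[[lt69]], [[ge69]]]),
        strata=("lt69", "ge69"),
        elderly=(False, True),
        geometry=GridGeometry(1, 1),
        country_id=np.zeros((1, 1), dtype=np.int64),
    )


class TestTotalGrowthFactors:
    def test_direct_ratio(self):
        base = single_cell_grid(80, 20)  # total 100
        gf = total_growth_factors(base, np.array([[150.0]]), "s")
        assert gf.gamma_total[0, 0] == pytest.approx(1.5)

    def test_projection_equal_to_base_gives_unity(self, rng):
        base = random_population(rng)
        gf = total_growth_factors(base, base.total(), "s")
        np.testing.assert_allclose(gf.gamma_total, 1.0, rtol=1e-14)

    def test_matches_cellwise_oracle(self, rng):
        base = random_population(rng, nrows=8, ncols=9)
        proj = rng.uniform(0, 300, size=base.geometry.shape)
        gf = total_growth_factors(base, proj, "s")
        for i in range(8):
            for j in range(9):
                expected = proj[i, j] / base.counts[:, i, j].sum()
                assert gf.gamma_total[i, j] == pytest.approx(expected, rel=1e-14)

    def test_zero_base_cells_get_country_mean(self, rng, caplog):
        base = random_population(rng, zero_cells=4)
        proj = rng.uniform(10, 300, size=base.geometry.shape)
        with caplog.at_level("WARNING"):
            gf = total_growth_factors(base, proj, "s")
        assert "zero base population" in caplog.text
        empty = base.total() == 0
        assert np.all(np.isfinite(gf.gamma_total[empty]))

    def test_grid_mismatch_and_negative_inputs_rejected(self, rng):
        base = random_population(rng)
        with pytest.raises(ValueError):
            total_growth_factors(base, np.ones((2, 2)), "s")
        bad = base.total().copy()
        bad[0, 0] = -1.0
        with pytest.raises(ValueError):
            total_growth_factors(base, bad, "s")


class TestCountryAgeAdjustments:
    def test_single_cell_country(self):
        base = single_cell_grid(lt69=90.0, ge69=10.0)
        gf = total_growth_factors(base, np.array([[100.0]]), "s")  # gamma = 1
        table = make_table([(0, "lt69", "s", 90.0), (0, "ge69", "s", 12.0)])
        gf = country_age_adjustments(base, gf, table)
        assert gf.lam[(0, "ge69")] == pytest.approx(1.2)
        assert gf.lam[(0, "lt69")] == pytest.approx(1.0)

    def test_matches_brute_force_sum_oracle(self, rng):
        base = random_population(rng, nrows=7, ncols=8, n_countries=2)
        proj = rng.uniform(10, 300, size=base.geometry.shape)
        gf = total_growth_factors(base, proj, "s")
        targets = [(c, a, "s", rng.uniform(100, 1000))
                   for c in range(2) for a in ("lt69", "ge69")]
        gf = country_age_adjustments(base, gf, make_table(targets))
        for c, a, _, target in targets:
            i = base.strata.index(a)
            denom = 0.0
            for r in range(7):
                for col in range(8):
                    if base.country_id[r, col] == c:
                        denom += gf.gamma_total[r, col] * base.counts[i, r, col]
            assert gf.lam[(c, a)] == pytest.approx(target / denom, rel=1e-12)

    def test_missing_country_row_names_country_and_stratum(self, rng):
        base = random_population(rng, n_countries=2)
        gf = total_growth_factors(base, base.total(), "s")
        table = make_table([(0, "lt69", "s", 10.0), (0, "ge69", "s", 10.0),
                            (1, "lt69", "s", 10.0)])
        with pytest.raises(KeyError, match="ge69"):
            country_age_adjustments(base, gf, table)


class TestProjectPopulation:
    def test_identity_factors_reproduce_base(self, rng):
        base = random_population(rng)
        targets = []
        for c in base.countries():
            mask = base.country_id == c
            for i, a in enumerate(base.strata):
                targets.append((int(c), a, "s", float(base.counts[i][mask].sum())))
        gf = total_growth_factors(base, base.total(), "s")
        gf = country_age_adjustments(base, gf, make_table(targets))
        out = project_population(base, gf)
        np.testing.assert_allclose(out.counts, base.counts, rtol=1e-12)

    def test_recovers_hidden_truth_on_homogeneous_inputs(self, small_config):
        pop = generate_population_inputs(small_config)
        for scen in small_config.scenarios:
            projected, _, _ = downscale(
                pop.base, pop.total_projection[scen],
                pop.country_projection, scen,
            )
            truth = pop.truth[scen].counts
            np.testing.assert_allclose(projected.counts, truth, rtol=1e-9)

    def test_country_age_sums_hit_targets(self, rng):
        base = random_population(rng, n_countries=3, zero_cells=3)
        proj = rng.uniform(0, 300, size=base.geometry.shape)
        targets = [(c, a, "s", rng.uniform(100, 5000))
                   for c in range(3) for a in ("lt69", "ge69")]
        table = make_table(targets)
        projected, _, _ = downscale(base, proj, table, "s")
        residual = constraint_residual(projected, table)
        assert residual["rel_error"].max() < 1e-9

    def test_zero_stratum_mass_distributed_uniformly(self, rng, caplog):
        base = random_population(rng, n_countries=1)
        base.counts[1] = 0.0  # no elderly anywhere
        base = PopulationGrid(
            counts=base.counts, strata=base.strata, elderly=base.elderly,
            geometry=base.geometry, country_id=base.country_id,
        )
        proj = base.total() * 1.1
        table = make_table([(0, "lt69", "s", float(base.counts[0].sum()) * 1.1),
                            (0, "ge69", "s", 500.0)])
        with caplog.at_level("WARNING"):
            projected, _, _ = downscale(base, proj, table, "s")
        assert "spread uniformly" in caplog.text
        assert projected.counts[1].sum() == pytest.approx(500.0, rel=1e-12)
        populated = base.total() > 0
        vals = projected.counts[1][populated]
        np.testing.assert_allclose(vals, vals[0])

    def test_scale_equivariance(self, rng):
        base = random_population(rng)
        proj = rng.uniform(10, 300, size=base.geometry.shape)
        targets = [(int(c), a, "s", rng.uniform(100, 5000))
                   for c in base.countries() for a in base.strata]
        out1, _, _ = downscale(base, proj, make_table(targets), "s")
        k = 3.7
        scaled_base = PopulationGrid(
            counts=base.counts * k, strata=base.strata, elderly=base.elderly,
            geometry=base.geometry, country_id=base.country_id,
        )
        scaled_targets = [(c, a, s, p * k) for c, a, s, p in targets]
        out2, _, _ = downscale(scaled_base, proj * k, make_table(scaled_targets), "s")
        np.testing.assert_allclose(out2.counts, out1.counts * k, rtol=1e-12)


class TestAgeFractions:
    def test_share_arithmetic(self):
        grid = single_cell_grid(lt69=80.0, ge69=20.0)
        assert age_fractions(grid).a_plus[0, 0] == pytest.approx(0.2)

    def test_all_elderly_boundary(self):
        grid = single_cell_grid(lt69=0.0, ge69=50.0)
        assert age_fractions(grid).a_plus[0, 0] == pytest.approx(1.0)

    def test_zero_population_is_undefined_not_zero(self):
        grid = single_cell_grid(lt69=0.0, ge69=0.0)
        assert np.isnan(age_fractions(grid).a_plus[0, 0])

    def test_shares_sum_to_one_and_match_oracle(self, rng):
        grid = random_population(rng, zero_cells=2)
        frac = age_fractions(grid)
        total = grid.total()
        pos = total > 0
        np.testing.assert_allclose(
            frac.a_plus[pos] + frac.a_minus[pos], 1.0, rtol=1e-14
        )
        np.testing.assert_allclose(
            frac.a_plus[pos], grid.counts[1][pos] / total[pos], rtol=1e-14
        )

    def test_uniform_growth_leaves_shares_invariant(self, rng):
        grid = random_population(rng)
        doubled = grid.with_counts(grid.counts * 2.0, year=2050, scenario="s")
        np.testing.assert_allclose(
            age_fractions(doubled).a_plus, age_fractions(grid).a_plus,
            rtol=1e-14,
        )
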