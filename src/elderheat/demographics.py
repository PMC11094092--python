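"""Constrained downscaling of age-stratified population projections.

The procedure imputes a mid-century gridded population by age stratum from
three inputs: a base-year age-stratified grid ``n_{a,g,0}``, a gridded
projection of *total* population per scenario ``N^tot_{g,s}``, and a
country-level age-stratified projection table ``N^ctry_{a,c,s}``. It runs in
two levels:

1. a per-cell total growth factor
   ``gamma^T_{g,s} = N^tot_{g,s} / sum_a n_{a,g,0}``;
2. a per-country, per-stratum adjustment
   ``lambda_{a,c,s} = N^ctry_{a,c,s} / sum_{g in c} gamma^T_{g,s} n_{a,g,0}``
   chosen so the projected grid reproduces the country-by-age totals
   exactly.

The projected grid is ``N*_{a,g,s} = lambda_{a,c(g),s} gamma^T_{g,s}
n_{a,g,0}``, from which per-cell 69+ population shares follow. The method
assumes age-stratum growth is geographically homogeneous within a country;
where that fails the constraint still holds but cell-level allocation is
biased (quantified by :mod:`elderheat.benchmark`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AgeFractionSurface, CountryAgeProjection, PopulationGrid
from .grids import NO_COUNTRY

__all__ = [
    "GrowthFactors",
    "total_growth_factors",
    "country_age_adjustments",
    "project_population",
    "age_fractions",
    "downscale",
]

log = logging.getLogger(__name__)

#: Relative tolerance at which the country-by-age constraint must hold.
CONSTRAINT_RTOL = 1e-9


@dataclass
class GrowthFactors:
    """Growth factors for one scenario.

    ``gamma_total`` is per-cell (NaN where undefined and unfilled);
    ``lam`` maps (country, stratum) -> adjustment; ``uniform_targets`` maps
    (country, stratum) -> persons to spread uniformly over the country's
    populated cells when the adjustment denominator is zero (no base
    population of that stratum anywhere in the country but a positive
    country target — the constraint takes precedence over proportionality).
    """

    scenario: str
    gamma_total: np.ndarray
    lam: dict = field(default_factory=dict)
    uniform_targets: dict = field(default_factory=dict)

    def combined(self, base: PopulationGrid) -> np.ndarray:
        """gamma*_{a,g} = lambda_{a,c(g)} * gamma^T_g (multiplicative part)."""
        out = np.zeros((base.n_strata, *base.geometry.shape))
        for c in base.countries():
            mask = base.country_id == c
            for i, stratum in enumerate(base.strata):
                lam = self.lam.get((int(c), stratum))
                if lam is not None:
                    out[i][mask] = lam * self.gamma_total[mask]
        return out


def total_growth_factors(
    base: PopulationGrid, total_projection: np.ndarray, scenario: str
) -> GrowthFactors:
    """Per-cell total-population growth factors (level 1).

    Cells with zero base population but a positive projected total have an
    undefined ratio; they receive their country's population-weighted mean
    growth factor (logged), so projected mass is not silently dropped.
    Cells with zero base and zero projection get gamma^T = 0.
    """
    total_projection = np.asarray(total_projection, dtype=np.float64)
    if total_projection.shape != base.geometry.shape:
        raise ValueError(
            f"projection grid {total_projection.shape} does not match base "
            f"grid {base.geometry.shape}"
        )
    if not np.all(np.isfinite(total_projection)) or np.any(total_projection < 0):
        raise ValueError("projected totals must be finite and non-negative")

    base_total = base.total()
    gamma = np.full(base.geometry.shape, np.nan)
    pos = base_total > 0
    gamma[pos] = total_projection[pos] / base_total[pos]
    gamma[(~pos) & (total_projection == 0)] = 0.0

    orphan = (~pos) & (total_projection > 0)
    if np.any(orphan):
        log.warning(
            "%d cells have zero base population but positive projected "
            "totals; assigning country-mean growth factors",
            int(orphan.sum()),
        )
        for c in np.unique(base.country_id[orphan]):
            in_c = base.country_id == c
            donors = in_c & pos
            if np.any(donors):
                mean_gamma = float(
                    np.average(gamma[donors], weights=base_total[donors])
                )
            else:
                mean_gamma = 1.0
            gamma[orphan & in_c] = mean_gamma
    return GrowthFactors(scenario=scenario, gamma_total=gamma)


def country_age_adjustments(
    base: PopulationGrid,
    factors: GrowthFactors,
    country_projection: CountryAgeProjection,
) -> GrowthFactors:
    """Country-level age-stratum adjustments (level 2), filled into ``factors``.

    Raises :class:`KeyError` naming the country and stratum if the
    projection table lacks a required row.
    """
    gamma = factors.gamma_total
    for c in base.countries():
        mask = base.country_id == c
        g = np.where(np.isfinite(gamma[mask]), gamma[mask], 0.0)
        for i, stratum in enumerate(base.strata):
            target = country_projection.lookup(int(c), stratum, factors.scenario)
            denom = float((g * base.counts[i][mask]).sum())
            if denom > 0:
                factors.lam[(int(c), stratum)] = target / denom
            else:
                factors.lam[(int(c), stratum)] = 0.0
                if target > 0:
                    factors.uniform_targets[(int(c), stratum)] = target
                    log.warning(
                        "country %s stratum %s: zero base mass but target %g "
                        "persons; will be spread uniformly over the country's "
                        "populated cells",
                        c, stratum, target,
                    )
    return factors


def project_population(base: PopulationGrid, factors: GrowthFactors,
                       year: int = 2050) -> PopulationGrid:
    """Apply combined growth factors; enforce country-by-age totals.

    The output satisfies
    ``sum_{g in c} N*_{a,g} == N^ctry_{a,c}`` to relative 1e-9 by
    construction of the adjustments. Zero-denominator strata (see
    :class:`GrowthFactors`) are distributed uniformly over the country's
    populated cells.
    """
    combined = factors.combined(base)
    counts = combined * base.counts
    if factors.uniform_targets:
        populated = base.total() > 0
        for (c, stratum), target in factors.uniform_targets.items():
            cells = (base.country_id == c) & populated
            n_cells = int(cells.sum())
            if n_cells == 0:
                cells = base.country_id == c
                n_cells = int(cells.sum())
            i = base.strata.index(stratum)
            counts[i][cells] += target / n_cells
    return base.with_counts(counts, year=year, scenario=factors.scenario)


def age_fractions(projected: PopulationGrid) -> AgeFractionSurface:
    """Per-cell 69+ share of the projected population.

    Cells with zero projected total are undefined (NaN), never coerced to 0.
    """
    total = projected.total()
    elderly = projected.elderly_count()
    with np.errstate(invalid="ignore", divide="ignore"):
        a_plus = np.where(total > 0, elderly / total, np.nan)
    return AgeFractionSurface(
        a_plus=a_plus,
        geometry=projected.geometry,
        scenario=projected.scenario,
        year=projected.year,
    )


def constraint_residual(
    projected: PopulationGrid, country_projection: CountryAgeProjection
) -> pd.DataFrame:
    """Relative error of country-by-age sums against targets (diagnostic)."""
    rows = []
    for c in projected.countries():
        mask = projected.country_id == c
        for i, stratum in enumerate(projected.strata):
            target = country_projection.lookup(int(c), stratum, projected.scenario)
            got = float(projected.counts[i][mask].sum())
            rel = abs(got - target) / target if target > 0 else abs(got)
            rows.append(
                {"country": int(c), "age_stratum": stratum,
                 "target": target, "projected": got, "rel_error": rel}
            )
    return pd.DataFrame(rows)


def downscale(
    base: PopulationGrid,
    total_projection: np.ndarray,
    country_projection: CountryAgeProjection,
    scenario: str,
    year: int = 2050,
) -> tuple[PopulationGrid, AgeFractionSurface, GrowthFactors]:
    """Full two-level procedure: factors, projection, and 69+ shares."""
    factors = total_growth_factors(base, total_projection, scenario)
    factors = country_age_adjustments(base, factors, country_projection)
    projected = project_population(base, factors, year=year)
    residual = constraint_residual(projected, country_projection)
    worst = residual["rel_error"].max() if len(residual) else 0.0
    if worst > CONSTRAINT_RTOL:
        log.warning("country-by-age constraint residual %.3e exceeds %.0e",
                    worst, CONSTRAINT_RTOL)
    return projected, age_fractions(projected), factors
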