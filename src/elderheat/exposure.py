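"""Population-weighted heat exposure surfaces and regional summaries.

Per-cell exposure combines the 69+ population with a heat metric:

* ``PDD = A+ * N * CDD``  (person-degree-days per year, chronic),
* ``PD95 = A+ * N * TMAX95``  (person-degrees, acute intensity),
* ``PHD = A+ * N * HD``  (person-hot-days per year, acute frequency),

where ``N`` is the cell's total population and ``A+`` its 69+ share, so
``A+ * N`` is the count of older adults. Regional exposure is the plain sum
of member cells. Exceedance curves count the population living in cells
whose metric meets or exceeds a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AgeFractionSurface, HeatMetricSurface, PopulationGrid
from .grids import NO_COUNTRY, block_mode, block_sum
from .weighted import (
    WeightedSummary,
    WeightedTTest,
    weighted_distribution_summary,
    weighted_t_test,
)

__all__ = [
    "ExposureSurface",
    "ExceedanceCurve",
    "EXPOSURE_NAMES",
    "align_population_to_climate_grid",
    "exposure_surface",
    "aggregate_regions",
    "exceedance_curve",
    "threshold_population_change",
    "derived_cdd_threshold",
    "regional_summary",
    "regional_t_test",
]

log = logging.getLogger(__name__)

#: Exposure family per heat metric.
EXPOSURE_NAMES = {"cdd": "pdd", "tmax95": "pd95", "hd": "phd"}

#: Benchmark thresholds for dangerous exposure (hot days/yr, degC, degC*day/yr).
DANGER_THRESHOLDS = {"hd": 30.0, "tmax95": 37.5, "cdd": 1200.0}


@dataclass
class ExposureSurface:
    """Per-cell person-weighted heat exposure for one stratum and scenario."""

    values: np.ndarray
    name: str
    metric: str
    stratum: str
    scenario: str
    model: str
    geometry: object

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError("exposure surface does not match geometry")


@dataclass
class ExceedanceCurve:
    """Population living in cells whose metric >= threshold, per threshold."""

    thresholds: np.ndarray
    counts: np.ndarray
    metric: str
    stratum: str
    scenario: str

    def at(self, threshold: float) -> float:
        idx = np.nonzero(np.isclose(self.thresholds, threshold))[0]
        if idx.size:
            return float(self.counts[idx[0]])
        if threshold < self.thresholds[0] or threshold > self.thresholds[-1]:
            raise ValueError(f"threshold {threshold} outside curve range")
        # step curve: count at x is the count at the smallest grid point >= x
        return float(self.counts[np.searchsorted(self.thresholds, threshold)])


def align_population_to_climate_grid(
    pop: PopulationGrid, climate_geometry
) -> PopulationGrid:
    """Block-sum a fine population grid onto the coarser climate grid.

    Mass-conserving: the grand total is unchanged to relative 1e-12. The
    coarse cell's country id is the population-weighted mode of its fine
    cells. A refinement factor of 1 is the identity.
    """
    factor = pop.geometry.refinement_factor_to(climate_geometry)
    if factor == 1:
        return pop
    counts = block_sum(pop.counts, factor)
    country = block_mode(pop.country_id, factor, weights=pop.total())
    aligned = PopulationGrid(
        counts=counts,
        strata=pop.strata,
        elderly=pop.elderly,
        geometry=climate_geometry,
        country_id=country,
        year=pop.year,
        scenario=pop.scenario,
    )
    fine_total = pop.counts.sum()
    coarse_total = aligned.counts.sum()
    if fine_total > 0 and abs(coarse_total - fine_total) > 1e-12 * fine_total:
        raise AssertionError("block aggregation lost population mass")
    return aligned


def _stratum_population(
    pop: PopulationGrid, fractions: AgeFractionSurface | None, stratum: str
) -> np.ndarray:
    """Per-cell persons in the requested broad stratum ('ge69' or 'lt69').

    When an :class:`AgeFractionSurface` is supplied the count is
    ``A+ * N`` (resp. ``(1 - A+) * N``) with NaN shares treated as zero
    population; otherwise the grid's own strata are summed.
    """
    if stratum not in ("ge69", "lt69"):
        raise ValueError("stratum must be 'ge69' or 'lt69'")
    if fractions is None:
        return pop.elderly_count() if stratum == "ge69" else pop.young_count()
    share = np.nan_to_num(fractions.a_plus, nan=0.0)
    total = pop.total()
    return total * (share if stratum == "ge69" else 1.0 - share)


def exposure_surface(
    metrics: HeatMetricSurface,
    pop: PopulationGrid,
    fractions: AgeFractionSurface | None = None,
    stratum: str = "ge69",
) -> ExposureSurface:
    """Cell-wise exposure product for one metric and age stratum."""
    if metrics.geometry != pop.geometry:
        raise ValueError("metric and population grids differ; align first")
    if fractions is not None and fractions.geometry != pop.geometry:
        raise ValueError("age-fraction and population grids differ")
    persons = _stratum_population(pop, fractions, stratum)
    return ExposureSurface(
        values=persons * metrics.values,
        name=EXPOSURE_NAMES[metrics.metric],
        metric=metrics.metric,
        stratum=stratum,
        scenario=metrics.scenario,
        model=metrics.model,
        geometry=metrics.geometry,
    )


def aggregate_regions(
    surface: ExposureSurface, region_map: np.ndarray,
    region_names: dict | None = None,
) -> pd.DataFrame:
    """Sum an exposure surface over a region partition.

    Populated cells (non-zero exposure) outside every region are summed
    under the label ``"unassigned"`` with a logged warning; a ``"World"``
    row holds the grand total, which equals the sum of all region rows.
    """
    region_map = np.asarray(region_map)
    if region_map.shape != surface.geometry.shape:
        raise ValueError("region map does not match surface grid")
    rows = []
    unassigned = (region_map == NO_COUNTRY) & (surface.values != 0)
    if np.any(unassigned):
        log.warning("%d cells with exposure are unmapped; reporting under "
                    "'unassigned'", int(unassigned.sum()))
        rows.append({"region": "unassigned",
                     "value": float(surface.values[unassigned].sum()),
                     "n_cells": int(unassigned.sum())})
    for r in np.unique(region_map[region_map != NO_COUNTRY]):
        mask = region_map == r
        name = region_names.get(int(r), str(int(r))) if region_names else str(int(r))
        rows.append({"region": name,
                     "value": float(surface.values[mask].sum()),
                     "n_cells": int(mask.sum())})
    rows.append({"region": "World", "value": float(surface.values.sum()),
                 "n_cells": int(surface.values.size)})
    out = pd.DataFrame(rows)
    out.insert(1, "exposure", surface.name)
    out.insert(2, "stratum", surface.stratum)
    out.insert(3, "scenario", surface.scenario)
    return out


def exceedance_curve(
    metrics: HeatMetricSurface,
    pop: PopulationGrid,
    fractions: AgeFractionSurface | None,
    stratum: str,
    thresholds: np.ndarray,
) -> ExceedanceCurve:
    """Population in cells whose metric >= threshold, for each threshold."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.ndim != 1 or np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be a 1-D ascending array")
    persons = _stratum_population(pop, fractions, stratum)
    m = metrics.values.ravel()
    w = persons.ravel()
    # sort once, cumulative-sum from the hot end
    order = np.argsort(m)
    m_sorted = m[order]
    w_tail = np.concatenate([np.cumsum(w[order][::-1])[::-1], [0.0]])
    idx = np.searchsorted(m_sorted, thresholds, side="left")
    counts = w_tail[idx]
    return ExceedanceCurve(
        thresholds=thresholds,
        counts=counts,
        metric=metrics.metric,
        stratum=stratum,
        scenario=metrics.scenario,
    )


def threshold_population_change(
    future: ExceedanceCurve, baseline: ExceedanceCurve, threshold: float
) -> float:
    """Persons newly living above a benchmark threshold (future - baseline)."""
    if future.metric != baseline.metric or future.stratum != baseline.stratum:
        raise ValueError("curves are not comparable")
    return future.at(threshold) - baseline.at(threshold)


def derived_cdd_threshold(
    cdd: HeatMetricSurface,
    tmax95: HeatMetricSurface,
    hot_tmax: float = 37.5,
    pop: PopulationGrid | None = None,
    fractions: AgeFractionSurface | None = None,
    stratum: str = "ge69",
    population_weighted: bool = False,
) -> float:
    """Mean CDD over cells whose historical TMAX95 exceeds ``hot_tmax``.

    This is how the dangerous-CDD benchmark (1200 degC*day/yr at full scale)
    is defined: the mean is unweighted by default, with a
    population-weighted variant available. Raises :class:`ValueError` when
    no cell qualifies (the statistic is undefined).
    """
    if cdd.geometry != tmax95.geometry:
        raise ValueError("CDD and TMAX95 surfaces on different grids")
    qualifying = tmax95.values > hot_tmax
    if not np.any(qualifying):
        raise ValueError(f"no cells with TMAX95 > {hot_tmax} degC; "
                         "derived CDD threshold undefined")
    if not population_weighted:
        return float(cdd.values[qualifying].mean())
    if pop is None:
        raise ValueError("population grid required for the weighted variant")
    persons = _stratum_population(pop, fractions, stratum)
    w = persons[qualifying]
    if w.sum() <= 0:
        raise ValueError("no population in qualifying cells")
    return float(np.average(cdd.values[qualifying], weights=w))


def regional_summary(
    metrics: HeatMetricSurface,
    pop: PopulationGrid,
    fractions: AgeFractionSurface | None,
    stratum: str,
    region_mask: np.ndarray,
) -> WeightedSummary:
    """Population-weighted boxplot statistics of a metric over a region."""
    persons = _stratum_population(pop, fractions, stratum)
    mask = np.asarray(region_mask, dtype=bool)
    return weighted_distribution_summary(metrics.values[mask], persons[mask])


def regional_t_test(
    metrics: HeatMetricSurface,
    pop: PopulationGrid,
    fractions: AgeFractionSurface | None,
    region_mask: np.ndarray,
) -> WeightedTTest:
    """Welch test of 69+ vs <69 population-weighted mean metric exposure."""
    mask = np.asarray(region_mask, dtype=bool)
    old = _stratum_population(pop, fractions, "ge69")[mask]
    young = _stratum_population(pop, fractions, "lt69")[mask]
    if old.sum() <= 0 or young.sum() <= 0:
        raise ValueError("both strata need positive population in the region")
    return weighted_t_test(metrics.values[mask], old, metrics.values[mask], young)
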