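"""Validation of downscaled 69+ projections against reference projections.

Sub-national reference projections (counties, NUTS-3 regions, provinces,
...) are compared with the downscaled grid aggregated to the same units.
Error metrics follow the standard projection-validation convention:

* per-unit APE = |ours - ref| / ref x 100 (undefined for zero-reference
  units, which are excluded and counted);
* MAPE = unweighted mean of per-unit APEs;
* total error = |sum(ours) - sum(ref)| in persons;
* percent error = total error / sum(ref) x 100.

References built under non-SSP scenario assumptions are flagged
(``ssp_consistent``) rather than rejected: part of any discrepancy is then
attributable to differing scenario assumptions, not to the downscaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PopulationGrid
from .grids import NO_COUNTRY

__all__ = [
    "ReferenceProjection",
    "ComparisonReport",
    "aggregate_to_units",
    "compare",
]

log = logging.getLogger(__name__)


@dataclass
class ReferenceProjection:
    """Reference per-unit 69+ counts for one source and scenario."""

    table: pd.DataFrame  # columns: unit, persons
    source: str
    scenario: str
    ssp_consistent: bool = True

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table)
        for col in ("unit", "persons"):
            if col not in self.table.columns:
                raise ValueError(f"reference table missing column {col!r}")
        if self.table["unit"].duplicated().any():
            raise ValueError("duplicate unit ids in reference table")
        persons = self.table["persons"].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(persons)) or np.any(persons < 0):
            raise ValueError("reference persons must be finite and non-negative")


@dataclass
class ComparisonReport:
    """Summary and per-unit errors of one comparison run."""

    source: str
    scenario: str
    total_error: float
    percent_error: float
    mape: float
    per_unit: pd.DataFrame
    n_units: int
    n_excluded_zero_ref: int
    ssp_consistent: bool = True


def aggregate_to_units(projected: PopulationGrid, unit_map: np.ndarray) -> pd.DataFrame:
    """Mass-conserving 69+ sums per sub-national unit.

    ``unit_map`` is an integer raster on the projection grid; cells labeled
    with the no-unit sentinel are excluded (a warning reports how many of
    them carry population).
    """
    unit_map = np.asarray(unit_map)
    if unit_map.shape != projected.geometry.shape:
        raise ValueError("unit map does not match projection grid")
    elderly = projected.elderly_count()
    uncovered = (unit_map == NO_COUNTRY) & (projected.total() > 0)
    if np.any(uncovered):
        log.warning("%d populated cells are not covered by any unit",
                    int(uncovered.sum()))
    units = np.unique(unit_map[unit_map != NO_COUNTRY])
    rows = [
        {"unit": int(u), "persons": float(elderly[unit_map == u].sum())}
        for u in units
    ]
    return pd.DataFrame(rows)


def compare(ours: pd.DataFrame, ref: ReferenceProjection) -> ComparisonReport:
    """APE/MAPE/total-error comparison of our per-unit counts to a reference.

    ``ours`` has columns (unit, persons). Units present in only one table
    raise an error; zero-reference units are excluded from APE (undefined)
    and counted in the report.
    """
    ours = pd.DataFrame(ours)
    merged = ours.merge(
        ref.table, on="unit", how="outer", suffixes=("_ours", "_ref"),
        indicator=True,
    )
    mismatched = merged[merged["_merge"] != "both"]
    if len(mismatched):
        raise ValueError(
            f"unit ids not shared by both tables: "
            f"{sorted(mismatched['unit'].tolist())[:10]}"
        )
    ours_v = merged["persons_ours"].to_numpy(dtype=np.float64)
    ref_v = merged["persons_ref"].to_numpy(dtype=np.float64)
    total_ref = ref_v.sum()
    if total_ref <= 0:
        raise ValueError("reference total is zero; percentage errors undefined")
    total_error = float(abs(ours_v.sum() - total_ref))
    percent_error = 100.0 * total_error / total_ref

    nonzero = ref_v > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        log.warning("%d zero-reference units excluded from APE", n_excluded)
    ape = np.abs(ours_v[nonzero] - ref_v[nonzero]) / ref_v[nonzero] * 100.0
    per_unit = pd.DataFrame(
        {
            "unit": merged["unit"][nonzero].to_numpy(),
            "ours": ours_v[nonzero],
            "ref": ref_v[nonzero],
            "ape": ape,
        }
    )
    return ComparisonReport(
        source=ref.source,
        scenario=ref.scenario,
        total_error=total_error,
        percent_error=float(percent_error),
        mape=float(ape.mean()) if len(ape) else float("nan"),
        per_unit=per_unit,
        n_units=int(nonzero.sum()),
        n_excluded_zero_ref=n_excluded,
        ssp_consistent=ref.ssp_consistent,
    )
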