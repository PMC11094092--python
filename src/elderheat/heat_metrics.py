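"""Per-cell chronic and acute heat metrics from daily temperature stacks.

Three indicators, all in degrees Celsius and computed per grid cell:

* **CDD** — cooling degree days: the annual sum of the positive excess of
  the daily *mean* temperature over a base threshold (24 degC by default),
  reported as the arithmetic mean over the epoch's years (degC*day/yr).
  A chronic-exposure measure.
* **TMAX95** — the 95th percentile of the pooled multi-year distribution of
  daily *maximum* temperatures (degC). Acute-exposure intensity.
* **HD** — hot days: days whose maximum temperature meets or exceeds a
  threshold (37.5 degC by default), reported per year (days/yr) with the raw
  epoch count kept as an auxiliary field. Acute-exposure frequency.

Percentiles use linear interpolation between order statistics (numpy's
default), fixed here for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .containers import DailyTemperatureEpoch, HeatMetricSurface

__all__ = [
    "CDD_THRESHOLD",
    "HOT_DAY_THRESHOLD",
    "cooling_degree_days",
    "tmax_percentile",
    "hot_day_frequency",
    "ensemble_median",
    "metric_surfaces",
]

#: Base temperature for cooling degree days (degC).
CDD_THRESHOLD = 24.0
#: Daily-maximum threshold classifying a day as "hot" (degC).
HOT_DAY_THRESHOLD = 37.5
#: Percentile of the daily-maximum distribution used for acute intensity.
TMAX_PERCENTILE = 95.0


def cooling_degree_days(
    epoch: DailyTemperatureEpoch, threshold: float = CDD_THRESHOLD
) -> HeatMetricSurface:
    """Epoch-mean annual cooling degree days per cell.

    Per year ``t``: ``CDD_t = sum_d max(0, Tmean_d - threshold)``; the
    surface holds the mean over the epoch's years and the per-year series
    rides along in ``aux['annual']``.
    """
    excess = np.maximum(0.0, epoch.by_year("tmean") - threshold)
    annual = excess.sum(axis=1)  # (years, rows, cols)
    return HeatMetricSurface(
        values=annual.mean(axis=0),
        metric="cdd",
        geometry=epoch.geometry,
        scenario=epoch.scenario,
        epoch=epoch.epoch,
        model=epoch.model,
        threshold=threshold,
        aux={"annual": annual},
    )


def tmax_percentile(
    epoch: DailyTemperatureEpoch, percentile: float = TMAX_PERCENTILE
) -> HeatMetricSurface:
    """Percentile of the pooled daily-maximum sample per cell (degC)."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    values = np.percentile(epoch.tmax, percentile, axis=0, method="linear")
    return HeatMetricSurface(
        values=values,
        metric="tmax95",
        geometry=epoch.geometry,
        scenario=epoch.scenario,
        epoch=epoch.epoch,
        model=epoch.model,
        threshold=percentile,
    )


def hot_day_frequency(
    epoch: DailyTemperatureEpoch, threshold: float = HOT_DAY_THRESHOLD
) -> HeatMetricSurface:
    """Days per year with daily maximum >= threshold (inclusive comparison).

    The raw count over the whole epoch is kept in ``aux['epoch_count']``.
    """
    count = (epoch.tmax >= threshold).sum(axis=0).astype(np.float64)
    return HeatMetricSurface(
        values=count / epoch.years,
        metric="hd",
        geometry=epoch.geometry,
        scenario=epoch.scenario,
        epoch=epoch.epoch,
        model=epoch.model,
        threshold=threshold,
        aux={"epoch_count": count},
    )


def ensemble_median(surfaces: list[HeatMetricSurface]) -> HeatMetricSurface:
    """Cell-wise median across climate models of one metric surface.

    With an even model count the median is the mean of the two central
    values; with one model it is the identity.
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    first = surfaces[0]
    for s in surfaces[1:]:
        if s.metric != first.metric:
            raise ValueError(
                f"mixed metrics in ensemble: {s.metric!r} vs {first.metric!r}"
            )
        if s.geometry != first.geometry:
            raise ValueError("mixed grids in ensemble")
        if s.scenario != first.scenario or s.epoch != first.epoch:
            raise ValueError("mixed scenarios/epochs in ensemble")
    stack = np.stack([s.values for s in surfaces])
    return HeatMetricSurface(
        values=np.median(stack, axis=0),
        metric=first.metric,
        geometry=first.geometry,
        scenario=first.scenario,
        epoch=first.epoch,
        model="ensemble-median",
        threshold=first.threshold,
        aux={"n_models": len(surfaces)},
    )


def metric_surfaces(
    epoch: DailyTemperatureEpoch,
    cdd_threshold: float = CDD_THRESHOLD,
    hd_threshold: float = HOT_DAY_THRESHOLD,
    percentile: float = TMAX_PERCENTILE,
) -> dict:
    """All three metric surfaces for one epoch, keyed by metric name."""
    return {
        "cdd": cooling_degree_days(epoch, cdd_threshold),
        "tmax95": tmax_percentile(epoch, percentile),
        "hd": hot_day_frequency(epoch, hd_threshold),
    }
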