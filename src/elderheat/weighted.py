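"""Population-weighted summary statistics.

Weights throughout are *frequency* weights — genuine person counts — so a
cell with weight ``w`` behaves like ``w`` identical observations of that
cell's metric value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "weighted_quantile",
    "weighted_mean_var",
    "WeightedSummary",
    "weighted_distribution_summary",
    "WeightedTTest",
    "weighted_t_test",
]


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Frequency-weighted quantile, linear interpolation between order stats.

    Exact frequency-weight generalization of numpy's default quantile: for
    integer weights it equals ``np.quantile(np.repeat(values, weights), q)``.
    A weight-``w`` observation occupies ``w`` consecutive ranks of the
    notional expanded sample; the quantile interpolates linearly between the
    expanded-sample order statistics at rank ``h = q * (W - 1)``.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.shape != weights.shape or values.ndim != 1:
        raise ValueError("values and weights must be equal-length 1-D arrays")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    mask = weights > 0
    if not np.any(mask):
        raise ValueError("all weights are zero")
    order = np.argsort(values[mask], kind="stable")
    v = values[mask][order]
    w = weights[mask][order]
    cum = np.cumsum(w)
    total = cum[-1]

    def value_at_rank(k: np.ndarray) -> np.ndarray:
        # expanded-sample order statistic: block i covers ranks
        # [cum_{i-1}, cum_i), so rank k belongs to the first block with
        # cum > k.
        idx = np.searchsorted(cum, k, side="right")
        return v[np.minimum(idx, v.size - 1)]

    q = np.atleast_1d(np.asarray(q, dtype=np.float64))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    h = q * (total - 1.0)
    lo = np.floor(h)
    hi = np.ceil(h)
    vlo = value_at_rank(lo)
    vhi = value_at_rank(hi)
    out = vlo + (h - lo) * (vhi - vlo)
    return out if out.size > 1 else float(out[0])


def weighted_mean_var(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """(mean, unbiased variance, effective n) under frequency weights.

    Variance uses the frequency-weight analogue of ``ddof=1``:
    ``sum w (x - m)^2 / (sum w - 1)``; effective n is ``sum w``.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    n_eff = float(weights.sum())
    if n_eff <= 0:
        raise ValueError("total weight must be positive")
    mean = float(np.average(values, weights=weights))
    if n_eff <= 1:
        return mean, np.nan, n_eff
    var = float((weights * (values - mean) ** 2).sum() / (n_eff - 1.0))
    return mean, var, n_eff


@dataclass(frozen=True)
class WeightedSummary:
    """Boxplot-style statistics of a weighted sample."""

    mean: float
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    total_weight: float


def weighted_distribution_summary(values: np.ndarray, weights: np.ndarray) -> WeightedSummary:
    """Population-weighted mean, quartiles and range of a metric sample.

    Raises :class:`ValueError` when the region carries no weight (the
    summary is undefined, not zero).
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    mask = weights > 0
    if not np.any(mask):
        raise ValueError("summary undefined: zero total weight")
    q25, med, q75 = weighted_quantile(values, weights, [0.25, 0.5, 0.75])
    mean, _, total = weighted_mean_var(values[mask], weights[mask])
    return WeightedSummary(
        mean=mean,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        minimum=float(values[mask].min()),
        maximum=float(values[mask].max()),
        total_weight=total,
    )


@dataclass(frozen=True)
class WeightedTTest:
    """Welch-style two-sample test with frequency weights."""

    statistic: float
    pvalue: float
    df: float
    mean_a: float
    mean_b: float
    n_a: float
    n_b: float


def weighted_t_test(
    values_a: np.ndarray,
    weights_a: np.ndarray,
    values_b: np.ndarray,
    weights_b: np.ndarray,
) -> WeightedTTest:
    """Welch two-sample t-test on frequency-weighted samples.

    Treating weights as person counts, this is the ordinary Welch test on
    the expanded person-level samples (each person observes their cell's
    metric): with equal unit weights it reduces exactly to
    ``scipy.stats.ttest_ind(equal_var=False)``. Degenerate variance (either
    group with effective n <= 1 or zero variance in both) raises
    :class:`ValueError`.
    """
    ma, va, na = weighted_mean_var(values_a, weights_a)
    mb, vb, nb = weighted_mean_var(values_b, weights_b)
    if not np.isfinite(va) or not np.isfinite(vb):
        raise ValueError("test undefined: a group has effective n <= 1")
    se2a, se2b = va / na, vb / nb
    se2 = se2a + se2b
    if se2 <= 0:
        raise ValueError("test undefined: zero variance in both groups")
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (se2a**2 / (na - 1.0) + se2b**2 / (nb - 1.0))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WeightedTTest(
        statistic=float(t), pvalue=float(p), df=float(df),
        mean_a=ma, mean_b=mb, n_a=na, n_b=nb,
    )
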