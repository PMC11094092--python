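"""Decomposition of regional exposure change into demographic and climatic drivers.

Regional exposure is a sum of three-factor products over cells,
``E_r = sum_g A_g N_g H_g`` (69+ share x total population x heat metric).
The fractional change ``dE/E0`` between a baseline and a scenario epoch is
split into an age-structure term, a population-size term and a climate
term. Three weighting schemes are provided:

* ``"paper"`` — scenario-weighted shares ``w_g = A1 N1 H1 / E_r0`` applied
  to per-cell fractional factor changes. Not an exact identity (factor
  cross-terms survive); the residual is always recorded.
* ``"baseline"`` — baseline exposure shares ``w_g = A0 N0 H0 / E_r0``;
  first-order exact, assigns a pure single-factor change entirely to that
  factor.
* ``"lmdi"`` — logarithmic-mean Divisia index weights
  ``L(E1_g, E0_g) ln(X1/X0) / E_r0`` with ``L`` the logarithmic mean;
  the three terms sum to ``dE/E0`` exactly for positive inputs.

Cells where a factor is zero in either epoch (e.g. places with no hot days
under the historical climate that acquire them under warming) have an
undefined fractional or logarithmic change; their whole exposure change is
reported separately as the *emergent* term rather than being silently
dropped, so ``eps_A + eps_N + eps_H + emergent + residual = dE/E0`` holds
under every scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecompositionResult",
    "fractional_changes",
    "decompose",
    "SCHEMES",
]

SCHEMES = ("paper", "baseline", "lmdi")

FACTORS = ("age", "population", "climate")


@dataclass(frozen=True)
class DecompositionResult:
    """Additive split of a region's fractional exposure change."""

    region: str
    scenario: str
    family: str
    scheme: str
    eps_age: float
    eps_population: float
    eps_climate: float
    total: float
    emergent: float
    residual: float
    #: numerators of the three terms in exposure units (persons x metric);
    #: under "lmdi" these negate exactly when base and scenario are swapped.
    abs_terms: dict = field(default_factory=dict)
    n_cells: int = 0
    n_emergent: int = 0

    @property
    def term_sum(self) -> float:
        return self.eps_age + self.eps_population + self.eps_climate


def fractional_changes(base: np.ndarray, scenario: np.ndarray) -> np.ndarray:
    """Cell-wise ``(x_s - x_0) / x_0``; NaN where the baseline is zero.

    Applies to heat metrics and to exposure products alike. Negative
    inputs are rejected: all decomposed quantities are non-negative by
    construction.
    """
    base = np.asarray(base, dtype=np.float64)
    scenario = np.asarray(scenario, dtype=np.float64)
    if base.shape != scenario.shape:
        raise ValueError("epoch grids differ in shape")
    if np.any(base < 0) or np.any(scenario < 0):
        raise ValueError("negative inputs are not decomposable")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(base > 0, (scenario - base) / base, np.nan)
    return out


def _logmean(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logarithmic mean L(x, y) = (x - y)/(ln x - ln y), L(x, x) = x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    same = np.isclose(x, y, rtol=1e-14, atol=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lm = (x - y) / (np.log(x) - np.log(y))
    return np.where(same, x, lm)


def decompose(
    a0: np.ndarray, n0: np.ndarray, h0: np.ndarray,
    a1: np.ndarray, n1: np.ndarray, h1: np.ndarray,
    scheme: str = "paper",
    region: str = "region",
    scenario: str = "scenario",
    family: str = "pdd",
) -> DecompositionResult:
    """Decompose ``dE/E0`` for one region, scenario and metric family.

    Inputs are 1-D (or raveled) per-cell arrays of the three factors in the
    baseline (``a0, n0, h0``) and scenario (``a1, n1, h1``) epochs, already
    restricted to the region's cells. Raises :class:`ValueError` when the
    baseline regional exposure is zero (the fractional change is undefined).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    arrs = [np.ravel(np.asarray(x, dtype=np.float64)) for x in (a0, n0, h0, a1, n1, h1)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("factor arrays differ in length")
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("factors must be non-negative")
    a0, n0, h0, a1, n1, h1 = arrs

    e0_cell = a0 * n0 * h0
    e1_cell = a1 * n1 * h1
    e0 = e0_cell.sum()
    e1 = e1_cell.sum()
    if e0 <= 0:
        raise ValueError("baseline regional exposure is zero; "
                         "fractional decomposition undefined")
    total = (e1 - e0) / e0

    # cells whose factor changes are all well-defined under the scheme
    if scheme == "lmdi":
        ok = (a0 > 0) & (n0 > 0) & (h0 > 0) & (a1 > 0) & (n1 > 0) & (h1 > 0)
    else:
        ok = (a0 > 0) & (n0 > 0) & (h0 > 0)
    emergent_mask = ~ok & ((e0_cell > 0) | (e1_cell > 0))
    emergent = float((e1_cell[emergent_mask] - e0_cell[emergent_mask]).sum() / e0)

    if scheme == "lmdi":
        lm = _logmean(e1_cell[ok], e0_cell[ok])
        terms = {
            "age": float((lm * np.log(a1[ok] / a0[ok])).sum()),
            "population": float((lm * np.log(n1[ok] / n0[ok])).sum()),
            "climate": float((lm * np.log(h1[ok] / h0[ok])).sum()),
        }
    else:
        w = (e1_cell[ok] if scheme == "paper" else e0_cell[ok])
        terms = {
            "age": float((w * (a1[ok] - a0[ok]) / a0[ok]).sum()),
            "population": float((w * (n1[ok] - n0[ok]) / n0[ok]).sum()),
            "climate": float((w * (h1[ok] - h0[ok]) / h0[ok]).sum()),
        }
    eps = {k: v / e0 for k, v in terms.items()}
    residual = total - (eps["age"] + eps["population"] + eps["climate"]) - emergent
    return DecompositionResult(
        region=region,
        scenario=scenario,
        family=family,
        scheme=scheme,
        eps_age=eps["age"],
        eps_population=eps["population"],
        eps_climate=eps["climate"],
        total=float(total),
        emergent=emergent,
        residual=float(residual),
        abs_terms=terms,
        n_cells=int(ok.sum()),
        n_emergent=int(emergent_mask.sum()),
    )
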