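"""Regular lat/lon grid geometry and block aggregation utilities.

Convention used throughout the package: cell-center registration, rows run
north to south (row 0 is the northernmost band), columns west to east.
``x_origin``/``y_origin`` are the coordinates of the *outer corner* of the
upper-left cell; the center of cell (i, j) is therefore
``(x_origin + (j + 0.5) * cell_size, y_origin - (i + 0.5) * cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GridGeometry", "block_sum", "block_mode", "NO_COUNTRY"]

#: Sentinel country/region id for cells that belong to no unit.
NO_COUNTRY = -1


@dataclass(frozen=True)
class GridGeometry:
    """Shape and georeferencing of a regular lat/lon grid."""

    nrows: int
    ncols: int
    cell_size: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError("cell_size must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def ncells(self) -> int:
        return self.nrows * self.ncols

    def refine(self, factor: int) -> "GridGeometry":
        """Geometry of the grid split into ``factor`` x ``factor`` sub-cells."""
        factor = _check_factor(factor)
        return replace(
            self,
            nrows=self.nrows * factor,
            ncols=self.ncols * factor,
            cell_size=self.cell_size / factor,
        )

    def coarsen(self, factor: int) -> "GridGeometry":
        """Inverse of :meth:`refine`; requires shape divisible by ``factor``."""
        factor = _check_factor(factor)
        if self.nrows % factor or self.ncols % factor:
            raise ValueError(
                f"grid shape {self.shape} is not divisible by factor {factor}; "
                "pre-resample the finer grid to an integer refinement of the "
                "coarser one before aligning"
            )
        return replace(
            self,
            nrows=self.nrows // factor,
            ncols=self.ncols // factor,
            cell_size=self.cell_size * factor,
        )

    def refinement_factor_to(self, coarse: "GridGeometry") -> int:
        """Integer number of this grid's cells per ``coarse`` cell per axis."""
        ratio = coarse.cell_size / self.cell_size
        factor = int(round(ratio))
        if factor < 1 or abs(ratio - factor) > 1e-9 * max(1.0, ratio):
            raise ValueError(
                f"cell size ratio {ratio} is not an integer refinement; "
                "pre-resample before aligning"
            )
        if (self.nrows != coarse.nrows * factor) or (self.ncols != coarse.ncols * factor):
            raise ValueError("grid extents do not nest")
        return factor

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape ``self.shape`` at cell centers."""
        lon = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        lat = self.y_origin - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()


def _check_factor(factor: int) -> int:
    if factor != int(factor) or factor < 1:
        raise ValueError(f"refinement factor must be an integer >= 1, got {factor}")
    return int(factor)


def block_sum(values: np.ndarray, factor: int) -> np.ndarray:
    """Mass-conserving aggregation: sum each ``factor`` x ``factor`` block.

    Works on the trailing two axes so stacked (stratum, row, col) arrays
    aggregate in one call.
    """
    factor = _check_factor(factor)
    arr = np.asarray(values, dtype=np.float64)
    nrows, ncols = arr.shape[-2:]
    if nrows % factor or ncols % factor:
        raise ValueError(
            f"array shape {arr.shape[-2:]} not divisible by factor {factor}"
        )
    lead = arr.shape[:-2]
    out = arr.reshape(*lead, nrows // factor, factor, ncols // factor, factor)
    return out.sum(axis=(-3, -1))


def block_mode(labels: np.ndarray, factor: int, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted modal label per ``factor`` x ``factor`` block.

    Used to carry an integer country-ID layer from a fine grid to a coarse
    one: the coarse cell inherits the label holding the largest share of the
    block's weight (population). Blocks with zero total weight fall back to
    the unweighted mode; ties break toward the smaller label id.
    """
    factor = _check_factor(factor)
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("labels must be 2-D")
    nrows, ncols = lab.shape
    if nrows % factor or ncols % factor:
        raise ValueError(f"label shape {lab.shape} not divisible by factor {factor}")
    w = np.ones_like(lab, dtype=np.float64) if weights is None else np.asarray(
        weights, dtype=np.float64
    )
    out = np.full((nrows // factor, ncols // factor), NO_COUNTRY, dtype=lab.dtype)
    for bi in range(out.shape[0]):
        for bj in range(out.shape[1]):
            sl = (slice(bi * factor, (bi + 1) * factor), slice(bj * factor, (bj + 1) * factor))
            block_labels = lab[sl].ravel()
            block_w = w[sl].ravel()
            if block_w.sum() <= 0:
                block_w = np.ones_like(block_w)
            ids = np.unique(block_labels)
            totals = np.array([block_w[block_labels == i].sum() for i in ids])
            out[bi, bj] = ids[np.argmax(totals)]
    return out
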