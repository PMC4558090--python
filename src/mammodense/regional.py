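"""Regional and zonal percent-density quantification on a 6x8 grid.

After segmentation the breast is cropped to its bounding box and divided
into 48 near-equal rectangular sub-regions (6 columns x 8 rows).  Each cell
carries a regional PD (percent of its breast pixels that are dense); cells
are addressed by 1-based ``(col, row)`` coordinates with column 1 at the
chest wall (posterior) and column 6 at the nipple side (anterior), rows top
to bottom.  Columns aggregate into three anatomical zones — posterior
(columns 1–2), middle (3–4), anterior (5–6) — whose zonal PD is the
unweighted mean of the member cells' regional PDs.

Right-breast images are mirrored first so that "anterior" is the same grid
side for both breasts; all downstream coordinates refer to this canonical
orientation (chest wall on the left of the array).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalGrid",
    "ZonalSummary",
    "normalize_orientation",
    "crop_to_bbox",
    "tile_grid",
    "default_zone_map",
    "zonal_summary",
]

ZONES = ("posterior", "middle", "anterior")


@dataclass
class RegionalGrid:
    """Per-cell breast/dense pixel counts and regional PD on the 6x8 lattice.

    Arrays are indexed ``[row, col]`` with row 0 at the top and col 0 at the
    chest wall.  ``regional_pd`` is 0 for cells without breast tissue; use
    ``empty`` to distinguish a truly 0 % cell from an empty one.
    """

    breast_px: np.ndarray
    dense_px: np.ndarray
    regional_pd: np.ndarray
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    row_edges: np.ndarray
    col_edges: np.ndarray

    @property
    def nrows(self) -> int:
        return self.breast_px.shape[0]

    @property
    def ncols(self) -> int:
        return self.breast_px.shape[1]

    @property
    def empty(self) -> np.ndarray:
        """Boolean [row, col] array marking cells with no breast tissue."""
        return self.breast_px == 0

    @property
    def overall_pd(self) -> float:
        return 100.0 * self.dense_px.sum() / self.breast_px.sum()

    def values(self, empty_policy: str = "zero") -> tuple[np.ndarray, np.ndarray]:
        """Flat (row-major) regional-PD vector for Moran's I.

        ``empty_policy="zero"`` keeps all N cells with empty cells entered
        as 0 (the default, keeping N = 48); ``"drop"`` removes empty cells
        and returns the kept flat indices for subsetting the weight matrix.
        """
        flat = self.regional_pd.ravel()
        if empty_policy == "zero":
            return flat.copy(), np.arange(flat.size)
        if empty_policy == "drop":
            keep = np.flatnonzero(~self.empty.ravel())
            return flat[keep], keep
        raise ValueError(f"unknown empty_policy {empty_policy!r}")

    def cell(self, col: int, row: int) -> tuple[int, int, float]:
        """(breast_px, dense_px, regional_pd) at 1-based (col, row)."""
        if not (1 <= col <= self.ncols and 1 <= row <= self.nrows):
            raise IndexError("coordinates are 1-based (col, row)")
        r, c = row - 1, col - 1
        return int(self.breast_px[r, c]), int(self.dense_px[r, c]), float(self.regional_pd[r, c])


@dataclass
class ZonalSummary:
    """Mean regional PD per anatomical zone; NaN flags a zone with no tissue."""

    posterior: float
    middle: float
    anterior: float

    def as_dict(self) -> dict[str, float]:
        return {"posterior": self.posterior, "middle": self.middle, "anterior": self.anterior}


def normalize_orientation(
    pixels: np.ndarray, mask: np.ndarray, laterality: str
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror right-breast images so the chest wall is always on the left.

    Left images pass through unchanged; applying the transform twice to a
    right image restores the input (involution).
    """
    if laterality == "L":
        return np.asarray(pixels), np.asarray(mask)
    if laterality == "R":
        return np.fliplr(np.asarray(pixels)), np.fliplr(np.asarray(mask))
    raise ValueError(f"unknown laterality {laterality!r}")


def crop_to_bbox(*arrays: np.ndarray, mask: np.ndarray):
    """Crop arrays to the tight bounding box of the mask.

    Returns ``(cropped_arrays..., cropped_mask, bbox)`` where bbox is the
    half-open ``(row0, row1, col0, col1)`` rectangle in the original frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    out = tuple(np.asarray(a)[r0:r1, c0:c1] for a in arrays)
    return (*out, mask[r0:r1, c0:c1], (r0, r1, c0, c1))


def _edges(length: int, nparts: int) -> np.ndarray:
    # Near-equal integer split; remainder pixels go to the last part.
    base = length // nparts
    edges = np.arange(nparts + 1) * base
    edges[-1] = length
    return edges


def tile_grid(
    dense_map: np.ndarray,
    mask: np.ndarray,
    ncols: int = 6,
    nrows: int = 8,
    bbox: tuple[int, int, int, int] | None = None,
) -> RegionalGrid:
    """Partition the cropped breast into the grid of rectangular sub-regions.

    Inputs must already be cropped to the mask bounding box (see
    :func:`crop_to_bbox`).  The box is split into ``ncols`` x ``nrows``
    near-equal rectangles (remainder rows/columns are absorbed by the last
    row/column); every bounding-box pixel belongs to exactly one cell, so
    per-cell pixel counts sum exactly to the totals.
    """
    mask = np.asarray(mask, dtype=bool)
    dense_map = np.asarray(dense_map, dtype=bool)
    if dense_map.shape != mask.shape:
        raise ValueError("dense_map and mask shapes differ")
    if (dense_map & ~mask).any():
        raise ValueError("dense_map must be a subset of the mask")
    h, w = mask.shape
    if h < nrows or w < ncols:
        raise ValueError(f"bounding box {h}x{w} smaller than grid {nrows}x{ncols}")

    row_edges = _edges(h, nrows)
    col_edges = _edges(w, ncols)
    # Sum pixel counts over each rectangle with two reduceat passes.
    breast = np.add.reduceat(np.add.reduceat(mask, row_edges[:-1], axis=0),
                             col_edges[:-1], axis=1)
    dense = np.add.reduceat(np.add.reduceat(dense_map, row_edges[:-1], axis=0),
                            col_edges[:-1], axis=1)
    with np.errstate(invalid="ignore"):
        pd = np.where(breast > 0, 100.0 * dense / np.maximum(breast, 1), 0.0)
    return RegionalGrid(
        breast_px=breast.astype(np.int64),
        dense_px=dense.astype(np.int64),
        regional_pd=pd,
        bbox=bbox if bbox is not None else (0, h, 0, w),
        row_edges=row_edges,
        col_edges=col_edges,
    )


def default_zone_map(ncols: int = 6, nrows: int = 8) -> dict[tuple[int, int], str]:
    """Default cell-to-zone assignment: equal-width column bands.

    Posterior = columns 1–2 (chest wall), middle = 3–4, anterior = 5–6
    (nipple side), every row alike.  Keys are 1-based ``(col, row)``.
    """
    if ncols % 3:
        raise ValueError("default zone map needs ncols divisible by 3")
    band = ncols // 3
    return {
        (c, r): ZONES[min((c - 1) // band, 2)]
        for c in range(1, ncols + 1)
        for r in range(1, nrows + 1)
    }


def zonal_summary(
    grid: RegionalGrid, zone_map: dict[tuple[int, int], str] | None = None
) -> ZonalSummary:
    """Unweighted mean regional PD over each zone's nonempty cells.

    Cells with no breast tissue are excluded from the mean; a zone whose
    cells are all empty is reported NaN (missing), never zero.
    """
    if zone_map is None:
        zone_map = default_zone_map(grid.ncols, grid.nrows)
    cells = {(c, r) for c in range(1, grid.ncols + 1) for r in range(1, grid.nrows + 1)}
    if set(zone_map) != cells:
        raise ValueError("zone map must assign every grid cell exactly once")
    if set(zone_map.values()) != set(ZONES):
        raise ValueError(f"zone map must use all zones {ZONES}")

    sums = {z: [] for z in ZONES}
    for (c, r), zone in zone_map.items():
        if not grid.empty[r - 1, c - 1]:
            sums[zone].append(grid.regional_pd[r - 1, c - 1])
    means = {z: (float(np.mean(v)) if v else float("nan")) for z, v in sums.items()}
    return ZonalSummary(posterior=means["posterior"], middle=means["middle"],
                        anterior=means["anterior"])
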