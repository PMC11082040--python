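"""Individual-tree detection from canopy height models.

The detector follows the variable-window local-maximum rule: the search
radius around each focal CHM cell scales with the cell's height value
(radius = 0.2 x height, in meters), and the focal cell is retained as a
treetop only if it is the greatest value within that radius.  Crowns are
delineated by marker-controlled watershed seeded at the treetops, and canopy
cover is the fraction of CHM cells at or above a crown height threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from uasforest.data import (
    INVENTORY_HEIGHT_M,
    CanopyHeightModel,
    NormalizedPointCloud,
    ParameterError,
    ValidationError,
)

__all__ = [
    "DetectedTree",
    "CrownSegmentation",
    "WINDOW_COEF",
    "chm_from_points",
    "variable_window_radius",
    "detect_treetops",
    "segment_crowns",
    "canopy_cover_from_chm",
]

#: search-window radius per meter of canopy height
WINDOW_COEF = 0.2


@dataclass(frozen=True)
class DetectedTree:
    """A treetop: cell-center coordinates and CHM height of the local maximum."""

    x_m: float
    y_m: float
    height_m: float
    row: int = -1
    col: int = -1


@dataclass
class CrownSegmentation:
    """Watershed crown labels aligned to a CHM (0 = non-crown)."""

    labels: np.ndarray
    crown_area_m2: dict[int, float]


def chm_from_points(
    cloud: NormalizedPointCloud,
    cell_size_m: float = 0.10,
    bounds: tuple[float, float, float, float] | None = None,
) -> CanopyHeightModel:
    """Rasterize a height-normalized cloud: each cell takes the max z of its points.

    Cells containing no points are 0 (open ground), matching a point-to-raster
    CHM at high point density.
    """
    if cell_size_m <= 0:
        raise ParameterError("cell_size_m must be > 0")
    pts = cloud.points
    if bounds is None:
        if len(pts) == 0:
            raise ValidationError("empty cloud and no bounds given")
        x0, y0 = pts[:, 0].min(), pts[:, 1].min()
        x1, y1 = pts[:, 0].max(), pts[:, 1].max()
    else:
        x0, y0, x1, y1 = bounds
    ncols = max(int(np.ceil((x1 - x0) / cell_size_m)), 1)
    nrows = max(int(np.ceil((y1 - y0) / cell_size_m)), 1)
    cols = np.floor((pts[:, 0] - x0) / cell_size_m).astype(int)
    rows = np.floor((pts[:, 1] - y0) / cell_size_m).astype(int)
    inside = (cols >= 0) & (cols < ncols) & (rows >= 0) & (rows < nrows)
    if bounds is not None and not inside.any():
        raise ValidationError("bounds do not cover any point")
    grid = np.zeros((nrows, ncols), dtype=np.float32)
    np.maximum.at(grid, (rows[inside], cols[inside]), pts[inside, 2].astype(np.float32))
    return CanopyHeightModel(values=grid, cell_size_m=cell_size_m, origin=(x0, y0))


def variable_window_radius(height_m: float) -> float:
    """Search radius (m) of the variable window at a given canopy height (m)."""
    if height_m < 0:
        raise ParameterError("height must be >= 0")
    return WINDOW_COEF * height_m


def _disk_offsets(radius_cells: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius_cells))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = (dr * dr + dc * dc) <= radius_cells * radius_cells
    return dr[keep], dc[keep]


def detect_treetops(
    chm: CanopyHeightModel, min_height_m: float = INVENTORY_HEIGHT_M
) -> list[DetectedTree]:
    """Extract treetops as variable-window local maxima of the CHM.

    A cell is a treetop iff its value is >= ``min_height_m`` and >= every cell
    whose center lies within ``variable_window_radius(value)`` of its own
    center.  On exact plateaus (equal values within each other's windows) the
    cell with the smallest (row, col) wins; the result is sorted by descending
    height (ties by row, col).
    """
    vals = chm.filled(0.0)
    nrows, ncols = vals.shape
    cand = vals >= min_height_m
    if not cand.any():
        return []
    # a treetop whose window reaches past the 8-neighborhood must also be a
    # 3x3 local max; prefilter those cells (the common case) cheaply
    diag = chm.cell_size_m * np.sqrt(2.0)
    local3 = ndimage.maximum_filter(vals, size=3, mode="constant", cval=-np.inf)
    needs_3x3 = vals * WINDOW_COEF >= diag
    cand &= ~needs_3x3 | (vals >= local3)

    rows, cols = np.nonzero(cand)
    order = np.lexsort((cols, rows, -vals[rows, cols]))
    rows, cols = rows[order], cols[order]

    accepted: list[tuple[int, int, float]] = []
    offsets_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r, c in zip(rows, cols):
        v = vals[r, c]
        radius_cells = WINDOW_COEF * v / chm.cell_size_m
        key = int(np.floor(radius_cells * 16))
        if key not in offsets_cache:
            offsets_cache[key] = _disk_offsets(radius_cells)
        dr, dc = offsets_cache[key]
        rr = r + dr
        cc = c + dc
        ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        window = vals[rr[ok], cc[ok]]
        if window.max(initial=v) > v:
            continue
        # plateau tie: an equal-valued treetop already accepted within this
        # window suppresses the later (larger row, col) cell
        # equal-valued accepted cells sit at the tail (descending processing order)
        tied = False
        r2 = radius_cells * radius_cells
        for ar, ac, av in reversed(accepted):
            if av != v:
                break
            if (ar - r) ** 2 + (ac - c) ** 2 <= r2:
                tied = True
                break
        if tied:
            continue
        accepted.append((r, c, float(v)))
    out = []
    for r, c, v in accepted:
        x, y = chm.cell_center(r, c)
        out.append(DetectedTree(x_m=float(x), y_m=float(y), height_m=v, row=r, col=c))
    return out


def segment_crowns(
    chm: CanopyHeightModel,
    treetops: list[DetectedTree],
    crown_min_height_m: float = INVENTORY_HEIGHT_M,
) -> CrownSegmentation:
    """Marker-controlled watershed crown delineation seeded at treetops.

    The watershed floods the inverted CHM restricted to cells at or above
    ``crown_min_height_m``; label i belongs to treetop i (1-based, in the
    order given).  Crown area is labeled-cell count times cell area.
    """
    from skimage.segmentation import watershed

    vals = chm.filled(0.0)
    markers = np.zeros(vals.shape, dtype=np.int32)
    for i, t in enumerate(treetops, start=1):
        r, c = (t.row, t.col)
        if r < 0:
            r, c = chm.world_to_index(t.x_m, t.y_m)
        if not (0 <= r < vals.shape[0] and 0 <= c < vals.shape[1]):
            raise ValidationError(f"treetop at ({t.x_m}, {t.y_m}) falls outside the CHM")
        markers[r, c] = i
    mask = vals >= crown_min_height_m
    if not treetops:
        labels = np.zeros(vals.shape, dtype=np.int32)
    else:
        labels = watershed(-vals, markers=markers, mask=mask)
    cell_area = chm.cell_size_m**2
    counts = np.bincount(labels.ravel(), minlength=len(treetops) + 1)
    areas = {i: float(counts[i] * cell_area) for i in range(1, len(treetops) + 1)}
    return CrownSegmentation(labels=labels, crown_area_m2=areas)


def canopy_cover_from_chm(
    chm: CanopyHeightModel, crown_min_height_m: float = INVENTORY_HEIGHT_M
) -> float:
    """Fraction of CHM cells at or above the crown height threshold."""
    vals = chm.filled(0.0)
    return float((vals >= crown_min_height_m).mean())
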