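"""Individuals, clumps, and openings (ICO) spatial structure.

Trees whose stems are within 6 m of one another are treated as having the
potential for interlocking crowns; clumps are the connected components of
that 6-m adjacency graph (an isolated tree is an "individual").  Clumps are
binned into the size classes individual / 2-4 / 5-9 / 10-15 / >15 trees, and
openings are described by the proportion of plot area in 3-m bands of
distance to the nearest stem, evaluated on a 1-m grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from uasforest.data import ParameterError, TreePlot

__all__ = [
    "ClumpAssignment",
    "CLUMP_CLASSES",
    "OPENING_BANDS",
    "assign_clumps",
    "clump_class",
    "clump_metrics",
    "opening_distribution",
    "structure_metrics_long",
]

#: clump size-class labels, ordered
CLUMP_CLASSES = ("individual", "2-4", "5-9", "10-15", ">15")

#: opening distance-band labels ([0,3), [3,6), [6,9), [9,12), [12,inf) m)
OPENING_BANDS = ("0-3", "3-6", "6-9", "9-12", ">12")


@dataclass
class ClumpAssignment:
    """Partition of a tree list into clumps under the interlocking-crown radius."""

    clump_of: dict[str, int]
    clump_sizes: dict[int, int]

    @property
    def n_clumps(self) -> int:
        return len(self.clump_sizes)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in self.clump_sizes}
        for tid, c in self.clump_of.items():
            out[c].append(tid)
        return out


def assign_clumps(plot: TreePlot, eps_m: float = 6.0) -> ClumpAssignment:
    """Assign each tree to a clump: connected components at stem distance <= eps.

    Equivalent to DBSCAN on stem coordinates with a 2-point neighborhood:
    any two stems within ``eps_m`` share a clump, membership is transitive,
    and a tree farther than ``eps_m`` from all others is a singleton.  Clump
    ids are assigned deterministically in order of each clump's smallest
    member tree_id.
    """
    if eps_m <= 0:
        raise ParameterError("eps_m must be positive")
    ids = [t.tree_id for t in plot.trees]
    n = len(ids)
    if n == 0:
        return ClumpAssignment(clump_of={}, clump_sizes={})
    xy = plot.xy()
    tree_index = cKDTree(xy)
    graph = tree_index.sparse_distance_matrix(tree_index, max_distance=eps_m)
    _, labels = connected_components(graph.tocsr(), directed=False)
    # relabel deterministically by the smallest member id within each component
    order = sorted(range(n), key=lambda i: ids[i])
    remap: dict[int, int] = {}
    for i in order:
        if labels[i] not in remap:
            remap[labels[i]] = len(remap)
    clump_of = {ids[i]: remap[labels[i]] for i in range(n)}
    sizes: dict[int, int] = {}
    for c in clump_of.values():
        sizes[c] = sizes.get(c, 0) + 1
    return ClumpAssignment(clump_of=clump_of, clump_sizes=sizes)


def clump_class(size: int) -> str:
    """Size class of a clump: individual, 2-4, 5-9, 10-15, or >15 trees."""
    if size < 1:
        raise ParameterError("clump size must be >= 1")
    if size == 1:
        return "individual"
    if size <= 4:
        return "2-4"
    if size <= 9:
        return "5-9"
    if size <= 15:
        return "10-15"
    return ">15"


def _dissolved_area(
    xs: np.ndarray, ys: np.ndarray, radii: np.ndarray, cell_size_m: float = 0.10
) -> float:
    """Union area (m2) of crown disks, rasterized at the CHM grain."""
    if len(xs) == 0:
        return 0.0
    x0 = float((xs - radii).min()) - cell_size_m
    y0 = float((ys - radii).min()) - cell_size_m
    x1 = float((xs + radii).max()) + cell_size_m
    y1 = float((ys + radii).max()) + cell_size_m
    ncols = max(int(np.ceil((x1 - x0) / cell_size_m)), 1)
    nrows = max(int(np.ceil((y1 - y0) / cell_size_m)), 1)
    mask = np.zeros((nrows, ncols), dtype=bool)
    for x, y, r in zip(xs, ys, radii):
        if r <= 0:
            continue
        c0 = max(int((x - r - x0) / cell_size_m), 0)
        c1 = min(int((x + r - x0) / cell_size_m) + 2, ncols)
        r0 = max(int((y - r - y0) / cell_size_m), 0)
        r1 = min(int((y + r - y0) / cell_size_m) + 2, nrows)
        cx = x0 + (np.arange(c0, c1) + 0.5) * cell_size_m
        cy = y0 + (np.arange(r0, r1) + 0.5) * cell_size_m
        dx = cx[None, :] - x
        dy = cy[:, None] - y
        mask[r0:r1, c0:c1] |= dx**2 + dy**2 <= r * r
    return float(mask.sum()) * cell_size_m**2


def clump_metrics(plot: TreePlot, assignment: ClumpAssignment) -> pd.DataFrame:
    """Per-clump structure metrics, one row per clump.

    Columns: clump_id, size, size_class, ba_pct (clump share of stand basal
    area, summing to 100 over all clumps), height_cv_pct (100 * sample SD /
    mean of member heights; NaN for singletons), crown_area_m2 (dissolved
    union of the member crown disks).
    """
    by_id = {t.tree_id: t for t in plot.trees}
    members = assignment.members()
    total_ba = sum(np.pi * (t.dbh_cm / 200.0) ** 2 for t in plot.trees if t.dbh_cm)
    rows = []
    for cid in sorted(members):
        trees = [by_id[tid] for tid in members[cid]]
        for t in trees:
            if t.dbh_cm is None or t.height_m is None:
                raise ParameterError(f"tree {t.tree_id!r} lacks DBH or height")
        ba = sum(np.pi * (t.dbh_cm / 200.0) ** 2 for t in trees)
        h = np.array([t.height_m for t in trees])
        cv = 100.0 * h.std(ddof=1) / h.mean() if len(h) >= 2 else np.nan
        radii = np.array(
            [t.crown_radius_m if t.crown_radius_m is not None else 0.0 for t in trees]
        )
        area = _dissolved_area(
            np.array([t.x_m for t in trees]), np.array([t.y_m for t in trees]), radii
        )
        rows.append(
            {
                "clump_id": cid,
                "size": len(trees),
                "size_class": clump_class(len(trees)),
                "ba_pct": 100.0 * ba / total_ba if total_ba > 0 else 0.0,
                "height_cv_pct": cv,
                "crown_area_m2": area,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clump_id", "size", "size_class", "ba_pct", "height_cv_pct", "crown_area_m2"],
    )


def opening_distribution(
    plot: TreePlot, grid_m: float = 1.0, band_m: float = 3.0
) -> dict[str, float]:
    """Proportion of plot area in bands of distance to the nearest stem.

    Distances are evaluated at the centers of a ``grid_m`` grid inside the
    plot bounds and binned into [0, band), [band, 2*band), ... with the last
    band open-ended ([12, inf) at the 3-m default).  Proportions sum to 1; an
    empty plot puts all area in the top band.
    """
    if grid_m <= 0 or band_m <= 0:
        raise ParameterError("grid_m and band_m must be positive")
    x0, y0, x1, y1 = plot.bounds
    xs = np.arange(x0 + grid_m / 2.0, x1, grid_m)
    ys = np.arange(y0 + grid_m / 2.0, y1, grid_m)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    n_bands = len(OPENING_BANDS)
    if len(plot) == 0:
        props = np.zeros(n_bands)
        props[-1] = 1.0
    else:
        d, _ = cKDTree(plot.xy()).query(pts)
        idx = np.minimum((d // band_m).astype(int), n_bands - 1)
        props = np.bincount(idx, minlength=n_bands) / len(pts)
    return {band: float(p) for band, p in zip(OPENING_BANDS, props)}


def structure_metrics_long(
    plots: list[TreePlot], eps_m: float = 6.0, grid_m: float = 1.0, band_m: float = 3.0
) -> pd.DataFrame:
    """Long-format ICO structure metrics over a set of plots.

    One row per observation with columns ``plot``, ``metric``, ``class``,
    ``value``.  Observation units follow the comparison design: clump counts,
    per-class mean dissolved crown area, and opening-band proportions are
    plot-level (one row per plot and class); basal-area share and height CV
    are clump-level (one row per clump).  Every clump class is emitted for the
    plot-level metrics (zero count / NaN area when absent) so plots remain
    comparable.
    """
    rows = []
    for plot in plots:
        assignment = assign_clumps(plot, eps_m=eps_m)
        cm = clump_metrics(plot, assignment)
        counts = cm["size_class"].value_counts()
        area_means = cm.groupby("size_class", observed=True)["crown_area_m2"].mean()
        for cls in CLUMP_CLASSES:
            rows.append(
                {"plot": plot.plot_id, "metric": "n_clumps", "class": cls,
                 "value": float(counts.get(cls, 0))}
            )
            rows.append(
                {"plot": plot.plot_id, "metric": "crown_area_m2", "class": cls,
                 "value": float(area_means.get(cls, np.nan))}
            )
        for _, r in cm.iterrows():
            rows.append(
                {"plot": plot.plot_id, "metric": "ba_pct", "class": r["size_class"],
                 "value": float(r["ba_pct"])}
            )
            if np.isfinite(r["height_cv_pct"]):
                rows.append(
                    {"plot": plot.plot_id, "metric": "height_cv_pct",
                     "class": r["size_class"], "value": float(r["height_cv_pct"])}
                )
        openings = opening_distribution(plot, grid_m=grid_m, band_m=band_m)
        for band, prop in openings.items():
            rows.append(
                {"plot": plot.plot_id, "metric": "opening_pct", "class": band,
                 "value": 100.0 * prop}
            )
    return pd.DataFrame(rows, columns=["plot", "metric", "class", "value"])
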