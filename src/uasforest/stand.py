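"""Stand-level summaries and paired stem-map/UAS comparison statistics.

Summaries are the standard inventory quantities: trees per hectare (TPH,
all trees and trees taller than 5 m), basal area (m2/ha), quadratic mean
diameter (QMD, cm), and canopy cover.  Paired tables of stem-map and UAS
values are compared with the convention error = UAS - stem map; percent
errors are averaged per plot (mean of per-plot ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from uasforest.data import (
    ParameterError,
    TreePlot,
    ValidationError,
    PAIRED_METRICS,
    validate_plot_summary_table,
)

__all__ = [
    "StandSummary",
    "stand_summary",
    "qmd_from_ba_tph",
    "dissolved_crown_cover",
    "compare_tables",
]


@dataclass(frozen=True)
class StandSummary:
    tph: float
    tph_gt5: float
    ba_m2ha: float
    qmd_cm: float | None
    cover_frac: float | None


def stand_summary(
    plot: TreePlot, area_ha: float | None = None, cover: float | None = None
) -> StandSummary:
    """Density, basal area, QMD and (optionally) canopy cover for one plot.

    ``ba = sum(pi * (dbh_cm / 200)^2) / area`` and ``qmd = sqrt(mean dbh^2)``;
    QMD is None for an empty plot.  Cover is passed through as supplied (a
    fraction from :func:`dissolved_crown_cover` or
    :func:`uasforest.detection.canopy_cover_from_chm`).
    """
    if area_ha is None:
        area_ha = plot.area_ha
    if not area_ha > 0:
        raise ParameterError("area_ha must be positive")
    n = len(plot)
    if n == 0:
        return StandSummary(0.0, 0.0, 0.0, None, cover)
    missing = [t.tree_id for t in plot.trees if t.dbh_cm is None]
    if missing:
        raise ValidationError(f"trees without DBH: {missing[:10]}")
    dbh = np.array([t.dbh_cm for t in plot.trees])
    h = plot.heights()
    ba = float(np.sum(np.pi * (dbh / 200.0) ** 2) / area_ha)
    return StandSummary(
        tph=n / area_ha,
        tph_gt5=float((h > 5.0).sum() / area_ha),
        ba_m2ha=ba,
        qmd_cm=float(np.sqrt(np.mean(dbh**2))),
        cover_frac=cover,
    )


def qmd_from_ba_tph(ba_m2ha: float, tph: float) -> float:
    """QMD (cm) implied by basal area (m2/ha) and stem density (trees/ha)."""
    if ba_m2ha <= 0 or tph <= 0:
        raise ParameterError("ba and tph must be positive")
    return 200.0 * float(np.sqrt(ba_m2ha / (np.pi * tph)))


def dissolved_crown_cover(
    plot: TreePlot,
    bounds: tuple[float, float, float, float] | None = None,
    cell_size_m: float = 0.10,
) -> float:
    """Canopy cover as the dissolved (union) area of circular crowns / plot area.

    Crown disks are rasterized at the CHM grain so overlap between crowns is
    counted once, mirroring how field crown ellipses are dissolved before
    computing cover.
    """
    if bounds is None:
        bounds = plot.bounds
    x0, y0, x1, y1 = bounds
    ncols = int(round((x1 - x0) / cell_size_m))
    nrows = int(round((y1 - y0) / cell_size_m))
    missing = [t.tree_id for t in plot.trees if t.crown_radius_m is None]
    if missing:
        raise ValidationError(f"trees without crown radius: {missing[:10]}")
    mask = np.zeros((nrows, ncols), dtype=bool)
    for t in plot.trees:
        r = t.crown_radius_m
        if r <= 0:
            continue
        c0 = max(int((t.x_m - r - x0) / cell_size_m), 0)
        c1 = min(int((t.x_m + r - x0) / cell_size_m) + 2, ncols)
        r0 = max(int((t.y_m - r - y0) / cell_size_m), 0)
        r1 = min(int((t.y_m + r - y0) / cell_size_m) + 2, nrows)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = x0 + (np.arange(c0, c1) + 0.5) * cell_size_m
        ys = y0 + (np.arange(r0, r1) + 0.5) * cell_size_m
        dx = xs[None, :] - t.x_m
        dy = ys[:, None] - t.y_m
        mask[r0:r1, c0:c1] |= dx**2 + dy**2 <= r * r
    return float(mask.mean()) if mask.size else 0.0


def compare_tables(table: pd.DataFrame) -> pd.DataFrame:
    """Paired-plot error statistics for each stand metric.

    ``table`` must carry, per plot, paired ``<metric>_sm`` / ``<metric>_uas``
    columns for qmd_cm, tph, tph_gt5, ba_m2ha and cover_pct.  Errors are
    UAS - stem map.  Returns one row per metric with:

    * ``me`` mean error and ``mpe_pct`` mean per-plot percent error,
    * ``mae`` / ``mape_pct`` mean absolute (percent) error,
    * ``rmse`` and ``rmse_pct``.

    Percent statistics are means of per-plot ratios relative to the stem-map
    value.  For canopy cover (already in percent) the unsigned statistics are
    percentage points.
    """
    validate_plot_summary_table(table)
    rows = []
    for metric in PAIRED_METRICS:
        sm = table[f"{metric}_sm"].to_numpy(dtype=float)
        uas = table[f"{metric}_uas"].to_numpy(dtype=float)
        diff = uas - sm
        pct = 100.0 * diff / sm
        rows.append(
            {
                "metric": metric,
                "n": len(diff),
                "me": float(diff.mean()),
                "mpe_pct": float(pct.mean()),
                "mae": float(np.abs(diff).mean()),
                "mape_pct": float(np.abs(pct).mean()),
                "rmse": float(np.sqrt((diff**2).mean())),
                "rmse_pct": float(np.sqrt((pct**2).mean())),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
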