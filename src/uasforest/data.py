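"""Domain types and file I/O for tree lists, canopy height models, and point clouds.

Conventions (fixed, never auto-converted):

* coordinates are plot-local meters with the origin at the lower-left corner;
* tree height and crown radius in meters, DBH in centimeters, basal area in
  m2/ha;
* canopy height model (CHM) grids are addressed ``values[row, col]`` with row 0
  at the *bottom* edge and cell centers at ``origin + (index + 0.5) * cell_size``.

Tree lists are comma-delimited UTF-8 CSV with a mandatory header.  CHM rasters
are single-band float32 GeoTIFF (ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags).  Point clouds are XYZ text or LAS 1.2 (point format 0).
"""

from __future__ import annotations

import importlib.resources
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ParameterError",
    "INVENTORY_HEIGHT_M",
    "TreeRecord",
    "TreePlot",
    "CanopyHeightModel",
    "NormalizedPointCloud",
    "read_tree_csv",
    "write_tree_csv",
    "read_chm_raster",
    "write_chm_raster",
    "read_point_cloud",
    "write_point_cloud",
    "load_plot_summary_fixture",
    "validate_plot_summary_table",
]

#: Minimum height (m) for a stem to enter the inventory (breast height).
INVENTORY_HEIGHT_M = 1.37


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ParameterError(ValueError):
    """A parameter value is outside its valid domain."""


Source = Literal["stem_map", "uas"]
DbhOrigin = Literal["measured", "extracted", "predicted"]

_TREE_COLUMNS = [
    "tree_id",
    "x_m",
    "y_m",
    "height_m",
    "dbh_cm",
    "crown_radius_m",
    "source",
    "dbh_origin",
]


@dataclass(frozen=True)
class TreeRecord:
    """A single tree: position, size, and provenance."""

    tree_id: str
    x_m: float
    y_m: float
    height_m: float
    dbh_cm: float | None = None
    crown_radius_m: float | None = None
    source: Source = "stem_map"
    dbh_origin: DbhOrigin | None = None

    def validate(self, min_height_m: float = INVENTORY_HEIGHT_M) -> None:
        if not np.isfinite(self.height_m) or self.height_m < min_height_m:
            raise ValidationError(
                f"tree {self.tree_id!r}: height {self.height_m} m below the "
                f"inventory threshold {min_height_m} m"
            )
        if self.dbh_cm is not None and not self.dbh_cm > 0:
            raise ValidationError(f"tree {self.tree_id!r}: dbh_cm must be > 0")
        if self.crown_radius_m is not None and self.crown_radius_m < 0:
            raise ValidationError(f"tree {self.tree_id!r}: crown_radius_m must be >= 0")


@dataclass
class TreePlot:
    """A stem-mapped or UAS-detected tree list on a rectangular plot.

    ``bounds`` is ``(x_min, y_min, x_max, y_max)`` in meters; the default is
    the 1-ha square plot used throughout.
    """

    plot_id: str
    trees: list[TreeRecord] = field(default_factory=list)
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def area_ha(self) -> float:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0) * (y1 - y0) / 10_000.0

    def validate(
        self,
        min_height_m: float = INVENTORY_HEIGHT_M,
        edge_buffer_m: float = 0.0,
    ) -> None:
        seen: set[str] = set()
        x0, y0, x1, y1 = self.bounds
        for t in self.trees:
            if t.tree_id in seen:
                raise ValidationError(f"duplicate tree_id {t.tree_id!r}")
            seen.add(t.tree_id)
            t.validate(min_height_m)
            if not (
                x0 - edge_buffer_m <= t.x_m <= x1 + edge_buffer_m
                and y0 - edge_buffer_m <= t.y_m <= y1 + edge_buffer_m
            ):
                raise ValidationError(
                    f"tree {t.tree_id!r} at ({t.x_m}, {t.y_m}) outside bounds {self.bounds}"
                )

    def xy(self) -> np.ndarray:
        """(n, 2) array of stem coordinates."""
        return np.array([(t.x_m, t.y_m) for t in self.trees], dtype=float).reshape(-1, 2)

    def heights(self) -> np.ndarray:
        return np.array([t.height_m for t in self.trees], dtype=float)

    def with_trees(self, trees: Iterable[TreeRecord]) -> "TreePlot":
        return replace(self, trees=list(trees))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tree_id": t.tree_id,
                "x_m": t.x_m,
                "y_m": t.y_m,
                "height_m": t.height_m,
                "dbh_cm": t.dbh_cm,
                "crown_radius_m": t.crown_radius_m,
                "source": t.source,
                "dbh_origin": t.dbh_origin,
            }
            for t in self.trees
        ]
        return pd.DataFrame(rows, columns=_TREE_COLUMNS)


@dataclass
class CanopyHeightModel:
    """Gridded canopy surface height above ground.

    ``values[row, col]`` with row 0 along the bottom (southern) edge; the cell
    center of ``(row, col)`` is ``origin + ((col, row) + 0.5) * cell_size_m``.
    """

    values: np.ndarray
    cell_size_m: float = 0.10
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValidationError("CHM values must be a 2-D grid")
        if not self.cell_size_m > 0:
            raise ParameterError("cell_size_m must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def data_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced; heights are clipped at 0."""
        out = np.where(self.data_mask(), self.values, fill)
        return np.maximum(out, 0.0)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size_m
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size_m
        return x, y

    def world_to_index(self, x: np.ndarray | float, y: np.ndarray | float):
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size_m).astype(int)
        return row, col


@dataclass
class NormalizedPointCloud:
    """Points (x, y, z) with z = height above ground in meters."""

    points: np.ndarray
    z_tolerance_m: float = 0.05

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    def validate(self) -> None:
        if len(self) and self.points[:, 2].min() < -self.z_tolerance_m:
            raise ValidationError(
                f"point z below -{self.z_tolerance_m} m: cloud is not height-normalized"
            )

    def slice_z(self, z_lo: float, z_hi: float) -> "NormalizedPointCloud":
        z = self.points[:, 2]
        keep = (z >= z_lo) & (z <= z_hi)
        return NormalizedPointCloud(self.points[keep], self.z_tolerance_m)


# ---------------------------------------------------------------------------
# Tree-list CSV


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_tree_csv(path: str | Path, source: Source | None = None) -> TreePlot:
    """Read a tree-list CSV into a :class:`TreePlot`.

    Mandatory columns: ``tree_id, x_m, y_m, height_m``.  ``dbh_cm``,
    ``crown_radius_m``, ``source`` and ``dbh_origin`` are optional; empty cells
    stay unset.  ``source`` (if given) overrides any per-row source column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"tree_id": str}, float_precision="round_trip")
    missing = {"tree_id", "x_m", "y_m", "height_m"} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing mandatory columns {sorted(missing)}")
    trees: list[TreeRecord] = []
    for i, row in df.iterrows():
        try:
            x = float(row["x_m"])
            y = float(row["y_m"])
            h = float(row["height_m"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}, row {i + 2}: non-numeric coordinate ({exc})")
        row_source = source or row.get("source") or "stem_map"
        origin = row.get("dbh_origin")
        if isinstance(origin, float) and np.isnan(origin):
            origin = None
        trees.append(
            TreeRecord(
                tree_id=str(row["tree_id"]),
                x_m=x,
                y_m=y,
                height_m=h,
                dbh_cm=_opt_float(row.get("dbh_cm")),
                crown_radius_m=_opt_float(row.get("crown_radius_m")),
                source=row_source,
                dbh_origin=origin,
            )
        )
    return TreePlot(plot_id=path.stem, trees=trees)


def write_tree_csv(plot: TreePlot, path: str | Path) -> None:
    """Write a tree list as CSV; optional fields that are unset become empty cells."""
    df = plot.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# CHM GeoTIFF

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_chm_raster(chm: CanopyHeightModel, path: str | Path) -> None:
    """Write a CHM as single-band float32 GeoTIFF (north-up)."""
    import tifffile

    nrows = chm.shape[0]
    s = float(chm.cell_size_m)
    # tie the raster's top-left corner to world coordinates
    top_y = chm.origin[1] + nrows * s
    tifffile.imwrite(
        str(path),
        np.flipud(chm.values).astype(np.float32),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, chm.origin[0], top_y, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, repr(float(chm.nodata))),
        ],
    )


def read_chm_raster(path: str | Path) -> CanopyHeightModel:
    """Read a single-band GeoTIFF CHM written by :func:`write_chm_raster`."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) != 1:
            raise FormatError(f"{path}: expected a single-band, single-page raster")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError(f"{path}: multi-band raster is not a CHM")
        arr = page.asarray()
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a 2-D single-band raster")
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        cell = float(scale_tag.value[0]) if scale_tag is not None else 0.10
        if tie_tag is not None:
            ox = float(tie_tag.value[3])
            oy = float(tie_tag.value[4]) - arr.shape[0] * cell
        else:
            ox = oy = 0.0
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    return CanopyHeightModel(
        values=np.flipud(arr), cell_size_m=cell, origin=(ox, oy), nodata=nodata
    )


# ---------------------------------------------------------------------------
# Point clouds: XYZ text and minimal LAS 1.2 (point format 0)

_XYZ_SUFFIXES = {".xyz", ".txt", ".csv"}
_LAS_HEADER_SIZE = 227
_LAS_POINT_SIZE = 20
_LAS_SCALE = 0.001


def read_point_cloud(path: str | Path) -> NormalizedPointCloud:
    """Read a point cloud from XYZ text (whitespace or comma delimited) or LAS 1.2."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _XYZ_SUFFIXES:
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        pts = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        if pts.shape[1] < 3:
            raise FormatError(f"{path.name}: XYZ text needs 3 columns, found {pts.shape[1]}")
        cloud = NormalizedPointCloud(pts[:, :3])
    elif suffix == ".las":
        cloud = _read_las(path)
    else:
        raise FormatError(f"{path.name}: unknown point-cloud extension {suffix!r}")
    cloud.validate()
    return cloud


def write_point_cloud(cloud: NormalizedPointCloud, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _XYZ_SUFFIXES:
        np.savetxt(path, cloud.points, fmt="%.6f")
    elif suffix == ".las":
        _write_las(cloud, path)
    else:
        raise FormatError(f"{path.name}: unknown point-cloud extension {suffix!r}")


def _read_las(path: Path) -> NormalizedPointCloud:
    raw = path.read_bytes()
    if raw[:4] != b"LASF":
        raise FormatError(f"{path.name}: not a LAS file")
    (offset_to_points,) = struct.unpack_from("<I", raw, 96)
    (point_format,) = struct.unpack_from("<B", raw, 104)
    (record_len,) = struct.unpack_from("<H", raw, 105)
    (n_points,) = struct.unpack_from("<I", raw, 107)
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)
    body = np.frombuffer(
        raw, dtype=np.uint8, count=n_points * record_len, offset=offset_to_points
    ).reshape(n_points, record_len)
    xyz_int = body[:, :12].copy().view("<i4").reshape(n_points, 3)
    pts = xyz_int * np.asarray(scales) + np.asarray(offsets)
    return NormalizedPointCloud(pts)


def _write_las(cloud: NormalizedPointCloud, path: Path) -> None:
    pts = cloud.points
    n = len(pts)
    offsets = pts.min(axis=0) if n else np.zeros(3)
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)
    struct.pack_into("<B", header, 104, 0)  # point format 0
    struct.pack_into("<H", header, 105, _LAS_POINT_SIZE)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, _LAS_SCALE, _LAS_SCALE, _LAS_SCALE)
    struct.pack_into("<3d", header, 155, *offsets)
    mx = pts.max(axis=0) if n else np.zeros(3)
    mn = pts.min(axis=0) if n else np.zeros(3)
    struct.pack_into("<6d", header, 179, mx[0], mn[0], mx[1], mn[1], mx[2], mn[2])
    records = np.zeros((n, _LAS_POINT_SIZE), dtype=np.uint8)
    xyz_int = np.round((pts - offsets) / _LAS_SCALE).astype("<i4")
    records[:, :12] = xyz_int.view(np.uint8).reshape(n, 12)
    path.write_bytes(bytes(header) + records.tobytes())


# ---------------------------------------------------------------------------
# Packaged paired plot-summary fixture

_FIXTURE_NAME = "plot_summary_table.csv"

#: paired (stem_map, uas) metric columns of the plot-summary table
PAIRED_METRICS = ("qmd_cm", "tph", "tph_gt5", "ba_m2ha", "cover_pct")


def load_plot_summary_fixture() -> pd.DataFrame:
    """Load the packaged paired stand-summary table.

    One row per 1-ha study plot (11 plots across the SGR, CT, FS-On and FS-Off
    thinning treatments), with stem-map and UAS values of quadratic mean
    diameter (cm), trees per hectare (all trees and trees > 5 m tall), basal
    area (m2/ha), and canopy cover (%).
    """
    ref = importlib.resources.files("uasforest") / "fixtures" / _FIXTURE_NAME
    try:
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    except FileNotFoundError as exc:  # pragma: no cover
        raise FormatError(f"packaged fixture {_FIXTURE_NAME} is missing") from exc
    validate_plot_summary_table(df)
    return df


def validate_plot_summary_table(df: pd.DataFrame) -> None:
    """Check the paired-table contract used by :func:`uasforest.stand.compare_tables`."""
    required = {"plot", "treatment"}
    for metric in PAIRED_METRICS:
        required |= {f"{metric}_sm", f"{metric}_uas"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"paired table missing columns {sorted(missing)}")
    numeric = df[[c for c in df.columns if c not in ("plot", "treatment")]]
    if numeric.isna().any().any():
        raise ValidationError("paired table has unpaired (missing) cells")
    if (numeric <= 0).any().any():
        raise ValidationError("paired table values must be positive")
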