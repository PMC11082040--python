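"""Synthetic stem-mapped stands, rendered CHMs, and detection-error perturbations.

The generator emulates 1-ha ponderosa-pine plots under four thinning
archetypes:

* **SGR** (small group retention): a few retained tree groups (parent-
  offspring clustering) over large dense regeneration patches — high
  horizontal and vertical heterogeneity;
* **CT** (commercial thinning from below): evenly spaced overstory under a
  hard minimum spacing (~4.9 m), little understory — low heterogeneity;
* **FS-On / FS-Off** (free selection): moderately clustered overstory with
  moderate regeneration, FS-On carrying more understory (greater vertical
  heterogeneity).

Heights are drawn per stratum from truncated log-normals; DBH and crown
radius follow height allometries; crowns are rendered into a CHM as
generalized paraboloids; a breast-height slice simulator produces stem
circles (plus branch clutter) for circle-fit DBH testing; and a
perturbation operator turns a truth stem map into a "UAS-detected" list
with class-specific false-negative deletions, spurious additions, position
and height noise, and small-tree ingrowth emulating the multi-year lag
between stem mapping and flight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from uasforest.data import (
    INVENTORY_HEIGHT_M,
    CanopyHeightModel,
    NormalizedPointCloud,
    ParameterError,
    TreePlot,
    TreeRecord,
)
from uasforest.dbh import SLICE_Z_RANGE_M
from uasforest.matching import dominance_class

__all__ = [
    "TreatmentArchetype",
    "AllometryParams",
    "PerturbationParams",
    "PerturbationOutcome",
    "ARCHETYPES",
    "generate_stem_map",
    "assign_allometry",
    "render_chm",
    "simulate_breast_height_slice",
    "perturb_to_uas",
]

#: (meanlog of height in m, sdlog, min m, max m) per stratum
HeightLaw = dict[str, tuple[float, float, float, float]]


@dataclass(frozen=True)
class TreatmentArchetype:
    """Spatial-process and height parameters of one treatment type."""

    name: str
    overstory_density: float  # trees/ha (target, heights >= ~5 m stratum)
    clump_parent_intensity: float  # parents/ha; 0 selects hard-core inhibition
    offspring_mean: float  # expected trees per parent (Thomas process)
    offspring_sd_m: float  # offspring dispersal scale (m)
    understory_patch_density: float  # trees/ha inside regeneration patches
    understory_patch_fraction: float  # fraction of plot area in patches
    min_spacing_m: float  # hard-core inhibition distance (m); overstory only
    height_law: HeightLaw = field(
        default_factory=lambda: {
            "overstory": (np.log(14.0), 0.30, 5.0, 35.0),
            "understory": (np.log(2.3), 0.40, INVENTORY_HEIGHT_M, 5.0),
        }
    )

    def validate(self) -> None:
        if min(
            self.overstory_density,
            self.clump_parent_intensity,
            self.offspring_mean,
            self.understory_patch_density,
        ) < 0:
            raise ParameterError("densities must be >= 0")
        if not 0 <= self.understory_patch_fraction <= 1:
            raise ParameterError("understory_patch_fraction must be in [0, 1]")
        if self.min_spacing_m < 0:
            raise ParameterError("min_spacing_m must be >= 0")
        implied = self.overstory_density + (
            self.understory_patch_density * self.understory_patch_fraction
        )
        if implied > 1e5:
            raise ParameterError(f"implied density {implied:.0f} trees/ha > 1e5")


#: treatment presets, loosely calibrated to the observed per-treatment
#: densities (overall TPH roughly 160-660 across archetypes)
ARCHETYPES: dict[str, TreatmentArchetype] = {
    "SGR": TreatmentArchetype(
        name="SGR",
        overstory_density=100.0,
        clump_parent_intensity=5.0,
        offspring_mean=20.0,
        offspring_sd_m=4.0,
        understory_patch_density=1400.0,
        understory_patch_fraction=0.20,
        min_spacing_m=0.0,
    ),
    "CT": TreatmentArchetype(
        name="CT",
        overstory_density=170.0,
        clump_parent_intensity=0.0,
        offspring_mean=0.0,
        offspring_sd_m=0.0,
        understory_patch_density=60.0,
        understory_patch_fraction=0.10,
        min_spacing_m=4.9,
        height_law={
            "overstory": (np.log(16.0), 0.22, 5.0, 35.0),
            "understory": (np.log(2.3), 0.40, INVENTORY_HEIGHT_M, 5.0),
        },
    ),
    "FS-On": TreatmentArchetype(
        name="FS-On",
        overstory_density=180.0,
        clump_parent_intensity=12.0,
        offspring_mean=15.0,
        offspring_sd_m=6.0,
        understory_patch_density=700.0,
        understory_patch_fraction=0.15,
        min_spacing_m=0.0,
    ),
    "FS-Off": TreatmentArchetype(
        name="FS-Off",
        overstory_density=200.0,
        clump_parent_intensity=12.0,
        offspring_mean=17.0,
        offspring_sd_m=6.0,
        understory_patch_density=350.0,
        understory_patch_fraction=0.15,
        min_spacing_m=0.0,
    ),
}


@dataclass(frozen=True)
class AllometryParams:
    """Height -> DBH power law and linear crown-radius allometry."""

    beta1: float = 4.29
    beta2: float = 0.68
    resid_sd_cm: float = 1.20
    crown_slope: float = 0.15
    crown_intercept_m: float = 0.5

    def validate(self) -> None:
        if self.beta1 <= 0 or self.beta2 <= 0 or self.resid_sd_cm < 0:
            raise ParameterError("allometry parameters out of range")


@dataclass(frozen=True)
class PerturbationParams:
    """Detection-error model applied to a truth stem map.

    ``fn_rate_by_class`` deletes truth trees per dominance class;
    ``fp_rate_by_class`` states the target false-positive *rate*
    FP / (TP + FP) per class — the generator adds
    ``round(n_surviving * p / (1 - p))`` spurious trees so that a matcher
    recovering all survivors observes rate p.  ``ingrowth_rate`` adds small
    (1.37-2.0 m) trees per hectare emulating regeneration crossing the
    inventory threshold between stem mapping and flight.
    """

    fn_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {"understory": 0.4, "intermediate": 0.1, "overstory": 0.03}
    )
    fp_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {"understory": 0.6, "intermediate": 0.15, "overstory": 0.05}
    )
    xy_sd_m: float = 0.5
    height_bias_m: float = 0.36
    height_sd_m: float = 0.8
    ingrowth_rate: float = 0.0

    def validate(self) -> None:
        for rates in (self.fn_rate_by_class, self.fp_rate_by_class):
            for v in rates.values():
                if not 0 <= v <= 1:
                    raise ParameterError("rates must be in [0, 1]")
        if self.xy_sd_m < 0 or self.height_sd_m < 0 or self.ingrowth_rate < 0:
            raise ParameterError("sds and ingrowth_rate must be >= 0")


@dataclass
class PerturbationOutcome:
    """A perturbed ("UAS-detected") tree list plus truth lineage for oracles."""

    plot: TreePlot
    lineage: dict[str, str | None]


# ---------------------------------------------------------------------------
# Stem-map generation


def _truncated_lognormal(
    rng: np.random.Generator, n: int, meanlog: float, sdlog: float, lo: float, hi: float
) -> np.ndarray:
    out = rng.lognormal(meanlog, sdlog, size=n)
    for _ in range(200):
        bad = (out < lo) | (out >= hi)
        if not bad.any():
            break
        out[bad] = rng.lognormal(meanlog, sdlog, size=int(bad.sum()))
    return np.clip(out, lo, np.nextafter(hi, lo))


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_spacing: float,
    existing: np.ndarray | None = None,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Sequential dart-throwing with a hard-core rejection radius."""
    x0, y0, x1, y1 = bounds
    pts: list[np.ndarray] = [] if existing is None else list(existing)
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_attempts):
            p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            if min_spacing <= 0 or not pts:
                break
            d2 = np.min(np.sum((np.asarray(pts) - p) ** 2, axis=1))
            if d2 >= min_spacing**2:
                break
        else:
            break  # plot jammed: give up on remaining trees
        pts.append(p)
        placed.append(p)
    return np.asarray(placed).reshape(-1, 2)


def generate_stem_map(
    archetype: TreatmentArchetype,
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0),
    seed: int = 0,
    plot_id: str | None = None,
) -> TreePlot:
    """Generate a stem-mapped plot under a treatment archetype.

    Overstory stems come from a Thomas-like parent-offspring process when
    ``clump_parent_intensity > 0`` (SGR / free selection) and from hard-core
    dart throwing at ``min_spacing_m`` otherwise (commercial thinning).
    Understory stems are placed inside randomly located circular regeneration
    patches covering ``understory_patch_fraction`` of the plot.  Heights are
    drawn per stratum from the archetype's truncated log-normal law.
    Deterministic for a given seed.
    """
    archetype.validate()
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = bounds
    area_ha = (x1 - x0) * (y1 - y0) / 10_000.0

    # --- overstory
    if archetype.clump_parent_intensity > 0:
        n_parents = rng.poisson(archetype.clump_parent_intensity * area_ha)
        parents = np.column_stack(
            [rng.uniform(x0, x1, n_parents), rng.uniform(y0, y1, n_parents)]
        )
        over_pts: list[np.ndarray] = []
        # per-parent offspring counts scaled so the expected total matches the
        # archetype's overstory density target
        per_parent = (
            archetype.overstory_density
            / max(archetype.clump_parent_intensity, 1e-12)
        )
        for p in parents:
            k = rng.poisson(per_parent)
            if k == 0:
                continue
            off = p + rng.normal(0.0, archetype.offspring_sd_m, size=(k, 2))
            # toroidal wrap keeps the realized density unbiased at plot edges
            off[:, 0] = x0 + np.mod(off[:, 0] - x0, x1 - x0)
            off[:, 1] = y0 + np.mod(off[:, 1] - y0, y1 - y0)
            over_pts.append(off)
        over = np.concatenate(over_pts) if over_pts else np.empty((0, 2))
    else:
        n_over = rng.poisson(archetype.overstory_density * area_ha)
        over = _dart_throw(rng, n_over, bounds, archetype.min_spacing_m)

    # --- understory regeneration patches
    under = np.empty((0, 2))
    if archetype.understory_patch_fraction > 0 and archetype.understory_patch_density > 0:
        patch_r = 8.0  # m, nominal regeneration-patch radius
        plot_area = (x1 - x0) * (y1 - y0)
        n_patches = max(
            int(round(archetype.understory_patch_fraction * plot_area / (np.pi * patch_r**2))),
            1,
        )
        centers = np.column_stack(
            [rng.uniform(x0, x1, n_patches), rng.uniform(y0, y1, n_patches)]
        )
        n_under = rng.poisson(
            archetype.understory_patch_density
            * archetype.understory_patch_fraction
            * area_ha
        )
        c = centers[rng.integers(n_patches, size=n_under)]
        r = patch_r * np.sqrt(rng.uniform(size=n_under))
        theta = rng.uniform(0, 2 * np.pi, size=n_under)
        under = c + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        under[:, 0] = x0 + np.mod(under[:, 0] - x0, x1 - x0)
        under[:, 1] = y0 + np.mod(under[:, 1] - y0, y1 - y0)

    trees: list[TreeRecord] = []
    laws = archetype.height_law
    h_over = _truncated_lognormal(rng, len(over), *laws["overstory"])
    h_under = _truncated_lognormal(rng, len(under), *laws["understory"])
    for i, ((x, y), h) in enumerate(zip(over, h_over)):
        trees.append(TreeRecord(f"o{i:04d}", float(x), float(y), float(h)))
    for i, ((x, y), h) in enumerate(zip(under, h_under)):
        trees.append(TreeRecord(f"u{i:04d}", float(x), float(y), float(h)))
    return TreePlot(
        plot_id=plot_id or f"{archetype.name}-seed{seed}", trees=trees, bounds=bounds
    )


def assign_allometry(
    plot: TreePlot, params: AllometryParams | None = None, seed: int = 0
) -> TreePlot:
    """Assign DBH (power law + Gaussian noise, truncated positive) and crown radius."""
    params = params or AllometryParams()
    params.validate()
    rng = np.random.default_rng(seed)
    out = []
    for t in plot.trees:
        if t.height_m <= 0:
            raise ParameterError(f"tree {t.tree_id!r} has non-positive height")
        dbh = params.beta1 * t.height_m**params.beta2
        if params.resid_sd_cm > 0:
            dbh += rng.normal(0.0, params.resid_sd_cm)
        dbh = max(dbh, 0.1)
        crown = max(params.crown_intercept_m + params.crown_slope * t.height_m, 0.3)
        out.append(
            replace(t, dbh_cm=float(dbh), crown_radius_m=float(crown), dbh_origin="measured")
        )
    return plot.with_trees(out)


# ---------------------------------------------------------------------------
# Rendering


def render_chm(
    plot: TreePlot, cell_size_m: float = 0.10, crown_exponent: float = 2.0
) -> CanopyHeightModel:
    """Render tree crowns into a CHM as generalized paraboloids.

    Each tree contributes ``h(r) = height * (1 - (r / crown_radius) ** e)``
    for ``r <= crown_radius``; a cell takes the maximum over trees (0 where no
    crown reaches).  The cell containing each stem is set to the full tree
    height so every apex is exact.
    """
    if cell_size_m <= 0:
        raise ParameterError("cell_size_m must be > 0")
    x0, y0, x1, y1 = plot.bounds
    ncols = int(round((x1 - x0) / cell_size_m))
    nrows = int(round((y1 - y0) / cell_size_m))
    grid = np.zeros((nrows, ncols), dtype=np.float32)
    for t in plot.trees:
        if t.crown_radius_m is None:
            raise ParameterError(f"tree {t.tree_id!r} lacks a crown radius")
        R = t.crown_radius_m
        c0 = max(int((t.x_m - R - x0) / cell_size_m), 0)
        c1 = min(int((t.x_m + R - x0) / cell_size_m) + 2, ncols)
        r0 = max(int((t.y_m - R - y0) / cell_size_m), 0)
        r1 = min(int((t.y_m + R - y0) / cell_size_m) + 2, nrows)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = x0 + (np.arange(c0, c1) + 0.5) * cell_size_m
        ys = y0 + (np.arange(r0, r1) + 0.5) * cell_size_m
        rr = np.hypot(xs[None, :] - t.x_m, ys[:, None] - t.y_m)
        surf = t.height_m * (1.0 - (rr / R) ** crown_exponent)
        surf[rr > R] = 0.0
        np.maximum(grid[r0:r1, c0:c1], surf.astype(np.float32), out=grid[r0:r1, c0:c1])
        sr = int((t.y_m - y0) / cell_size_m)
        sc = int((t.x_m - x0) / cell_size_m)
        if 0 <= sr < nrows and 0 <= sc < ncols:
            grid[sr, sc] = max(grid[sr, sc], t.height_m)
    return CanopyHeightModel(values=grid, cell_size_m=cell_size_m, origin=(x0, y0))


def simulate_breast_height_slice(
    plot: TreePlot,
    pts_per_stem: int = 24,
    radial_sd_m: float = 0.0,
    clutter_fraction: float = 0.0,
    seed: int = 0,
) -> NormalizedPointCloud:
    """Simulate the 1.32-1.42 m slice of a photogrammetric point cloud.

    Every tree taller than the slice top contributes ``pts_per_stem`` points
    on its breast-height stem circle (radius dbh/200 m) with radial Gaussian
    noise; ``clutter_fraction`` adds spurious branch-like points uniform
    within crown disks at slice heights.
    """
    if pts_per_stem < 3:
        raise ParameterError("pts_per_stem must be >= 3 (circle fit underdetermined)")
    if not 0 <= clutter_fraction <= 1:
        raise ParameterError("clutter_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    z_lo, z_hi = SLICE_Z_RANGE_M
    pts: list[np.ndarray] = []
    stems = [t for t in plot.trees if t.height_m > z_hi]
    for t in stems:
        if t.dbh_cm is None:
            raise ParameterError(f"tree {t.tree_id!r} lacks DBH")
        r = t.dbh_cm / 200.0
        theta = rng.uniform(0, 2 * np.pi, pts_per_stem)
        rad = r + (rng.normal(0.0, radial_sd_m, pts_per_stem) if radial_sd_m > 0 else 0.0)
        x = t.x_m + rad * np.cos(theta)
        y = t.y_m + rad * np.sin(theta)
        z = rng.uniform(z_lo, z_hi, pts_per_stem)
        pts.append(np.column_stack([x, y, z]))
    n_clutter = int(round(clutter_fraction * pts_per_stem * len(stems)))
    crowned = [t for t in stems if t.crown_radius_m]
    for _ in range(n_clutter):
        t = crowned[rng.integers(len(crowned))] if crowned else None
        if t is None:
            break
        rad = t.crown_radius_m * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        pts.append(
            np.array(
                [[t.x_m + rad * np.cos(theta), t.y_m + rad * np.sin(theta),
                  rng.uniform(z_lo, z_hi)]]
            )
        )
    cloud = np.concatenate(pts) if pts else np.empty((0, 3))
    return NormalizedPointCloud(cloud)


# ---------------------------------------------------------------------------
# Detection-error perturbation

_CLASS_HEIGHT_RANGES = {
    "understory": (INVENTORY_HEIGHT_M, 5.0),
    "intermediate": (5.0, 15.0),
    "overstory": (15.0, 28.0),
}


def perturb_to_uas(
    plot: TreePlot, params: PerturbationParams | None = None, seed: int = 0
) -> PerturbationOutcome:
    """Perturb a truth stem map into a "UAS-detected" tree list.

    Deletes truth trees per dominance class (false negatives), jitters the
    survivors' positions and heights, and adds class-targeted spurious trees
    plus uniformly placed ingrowth.  The outcome records each output tree's
    truth ancestor (None for spurious/ingrowth) for test oracles.
    """
    params = params or PerturbationParams()
    params.validate()
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = plot.bounds
    out: list[TreeRecord] = []
    lineage: dict[str, str | None] = {}
    surviving_by_class: dict[str, int] = {c: 0 for c in _CLASS_HEIGHT_RANGES}
    for t in plot.trees:
        cls = dominance_class(t.height_m)
        if rng.uniform() < params.fn_rate_by_class.get(cls, 0.0):
            continue
        surviving_by_class[cls] += 1
        x, y, h = t.x_m, t.y_m, t.height_m
        if params.xy_sd_m > 0:
            x += rng.normal(0.0, params.xy_sd_m)
            y += rng.normal(0.0, params.xy_sd_m)
        h += params.height_bias_m
        if params.height_sd_m > 0:
            h += rng.normal(0.0, params.height_sd_m)
        rec = replace(
            t,
            x_m=float(np.clip(x, x0, x1)),
            y_m=float(np.clip(y, y0, y1)),
            height_m=float(max(h, INVENTORY_HEIGHT_M)),
            source="uas",
        )
        out.append(rec)
        lineage[rec.tree_id] = t.tree_id
    k = 0
    for cls, n_surv in surviving_by_class.items():
        p = params.fp_rate_by_class.get(cls, 0.0)
        if p <= 0 or n_surv == 0:
            continue
        n_spur = int(round(n_surv * p / (1.0 - p))) if p < 1 else 0
        lo, hi = _CLASS_HEIGHT_RANGES[cls]
        for _ in range(n_spur):
            rec = TreeRecord(
                tree_id=f"fp{k:04d}",
                x_m=float(rng.uniform(x0, x1)),
                y_m=float(rng.uniform(y0, y1)),
                height_m=float(rng.uniform(lo, hi)),
                source="uas",
            )
            out.append(rec)
            lineage[rec.tree_id] = None
            k += 1
    n_ingrowth = rng.poisson(params.ingrowth_rate * plot.area_ha)
    for i in range(n_ingrowth):
        rec = TreeRecord(
            tree_id=f"in{i:04d}",
            x_m=float(rng.uniform(x0, x1)),
            y_m=float(rng.uniform(y0, y1)),
            height_m=float(rng.uniform(INVENTORY_HEIGHT_M, 2.0)),
            source="uas",
        )
        out.append(rec)
        lineage[rec.tree_id] = None
    uas = TreePlot(plot_id=f"{plot.plot_id}-uas", trees=out, bounds=plot.bounds)
    return PerturbationOutcome(plot=uas, lineage=lineage)
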