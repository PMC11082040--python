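"""End-to-end orchestration: simulate -> detect -> dbh -> match -> summarize
-> clumps/openings -> anova.

Every stage writes its artifacts (tree CSVs, CHM GeoTIFFs, match and rate
tables, long-format structure metrics, the ANOVA table) into a run
directory, and a manifest records parameters, seeds, stage order and content
hashes so a rerun with the same config is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from uasforest import __version__
from uasforest.anova import compare_structure_metrics
from uasforest.data import TreePlot, TreeRecord, write_chm_raster, write_tree_csv
from uasforest.dbh import (
    PowerModel,
    extract_dbh,
    filter_pairs_by_bounds,
    fit_power_model,
    impute_missing_dbh,
    make_synthetic_regional_model,
)
from uasforest.detection import (
    DetectedTree,
    canopy_cover_from_chm,
    detect_treetops,
    segment_crowns,
)
from uasforest.matching import detection_rates, error_summary, match_trees
from uasforest.spatial import structure_metrics_long
from uasforest.stand import dissolved_crown_cover, stand_summary
from uasforest.synthetic import (
    ARCHETYPES,
    AllometryParams,
    assign_allometry,
    generate_stem_map,
    render_chm,
    simulate_breast_height_slice,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("uasforest")

STAGES = ("simulate", "detect", "dbh", "match", "summarize", "clumps", "openings", "anova")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "run"
    archetypes: tuple[str, ...] = ("SGR", "CT", "FS-On", "FS-Off")
    n_plots: int = 4
    seed: int = 0
    plot_size_m: float = 100.0
    cell_size_m: float = 0.10
    min_height_m: float = 1.37
    match_max_dist_m: float = 4.0
    match_max_height_err_m: float = 2.0
    clump_eps_m: float = 6.0
    opening_grid_m: float = 1.0
    opening_band_m: float = 3.0
    prediction_level: float = 0.90
    slice_pts_per_stem: int = 24
    slice_radial_sd_m: float = 0.005
    slice_clutter_fraction: float = 0.10
    regional_model_json: str | None = None  # None -> synthetic stand-in model

    def validate(self) -> None:
        positive = {
            "n_plots": self.n_plots,
            "plot_size_m": self.plot_size_m,
            "cell_size_m": self.cell_size_m,
            "min_height_m": self.min_height_m,
            "match_max_dist_m": self.match_max_dist_m,
            "match_max_height_err_m": self.match_max_height_err_m,
            "clump_eps_m": self.clump_eps_m,
            "opening_grid_m": self.opening_grid_m,
            "opening_band_m": self.opening_band_m,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"config field {name} must be positive, got {v}")
        if not 0 < self.prediction_level < 1:
            raise ValueError("prediction_level must be in (0, 1)")
        for a in self.archetypes:
            if a not in ARCHETYPES:
                raise ValueError(f"unknown archetype {a!r}; known: {sorted(ARCHETYPES)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic workflow; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "artifacts": {},
    }
    size = config.plot_size_m
    bounds = (0.0, 0.0, size, size)

    def finish_stage(name: str, files: list[Path]) -> None:
        manifest["stages"].append(name)
        for f in files:
            manifest["artifacts"][str(f.relative_to(out))] = _sha256(f)
        log.info("stage %s complete (%d artifacts)", name, len(files))

    try:
        # --- simulate --------------------------------------------------
        stem_plots: list[TreePlot] = []
        files = []
        for i in range(config.n_plots):
            arch = ARCHETYPES[config.archetypes[i % len(config.archetypes)]]
            plot = generate_stem_map(
                arch, bounds=bounds, seed=config.seed + i, plot_id=f"{arch.name}-{i}"
            )
            plot = assign_allometry(plot, AllometryParams(), seed=config.seed + 1000 + i)
            path = out / f"stem_{plot.plot_id}.csv"
            write_tree_csv(plot, path)
            stem_plots.append(plot)
            files.append(path)
        finish_stage("simulate", files)

        # --- detect ----------------------------------------------------
        uas_plots: list[TreePlot] = []
        covers_uas: list[float] = []
        files = []
        for plot in stem_plots:
            chm = render_chm(plot, cell_size_m=config.cell_size_m)
            tops = detect_treetops(chm, min_height_m=config.min_height_m)
            segment_crowns(chm, tops, crown_min_height_m=config.min_height_m)
            covers_uas.append(canopy_cover_from_chm(chm, config.min_height_m))
            trees = [
                TreeRecord(
                    tree_id=f"d{j:05d}", x_m=t.x_m, y_m=t.y_m,
                    height_m=t.height_m, source="uas",
                )
                for j, t in enumerate(tops)
            ]
            uas = TreePlot(plot_id=f"{plot.plot_id}-uas", trees=trees, bounds=bounds)
            chm_path = out / f"chm_{plot.plot_id}.tif"
            write_chm_raster(chm, chm_path)
            uas_path = out / f"uas_{plot.plot_id}.csv"
            write_tree_csv(uas, uas_path)
            uas_plots.append(uas)
            files += [chm_path, uas_path]
        finish_stage("detect", files)

        # --- dbh -------------------------------------------------------
        if config.regional_model_json:
            regional = PowerModel.from_json(config.regional_model_json)
        else:
            regional = make_synthetic_regional_model(seed=config.seed + 7)
        regional_path = out / "regional_model.json"
        regional.to_json(regional_path)
        files = [regional_path]
        uas_with_dbh: list[TreePlot] = []
        dbh_log = []
        for i, (stem, uas) in enumerate(zip(stem_plots, uas_plots)):
            slice_cloud = simulate_breast_height_slice(
                stem,
                pts_per_stem=config.slice_pts_per_stem,
                radial_sd_m=config.slice_radial_sd_m,
                clutter_fraction=config.slice_clutter_fraction,
                seed=config.seed + 2000 + i,
            )
            extracted: dict[str, float] = {}
            for t in uas.trees:
                fit = extract_dbh(
                    slice_cloud, DetectedTree(x_m=t.x_m, y_m=t.y_m, height_m=t.height_m)
                )
                if fit is not None:
                    extracted[t.tree_id] = fit.dbh_cm
            pairs = [(t.height_m, extracted[t.tree_id]) for t in uas.trees if t.tree_id in extracted]
            kept = filter_pairs_by_bounds(pairs, regional, level=config.prediction_level)
            kept_set = {(round(h, 9), round(d, 9)) for h, d in kept}
            trees = []
            for t in uas.trees:
                d = extracted.get(t.tree_id)
                if d is not None and (round(t.height_m, 9), round(d, 9)) in kept_set:
                    trees.append(dataclasses.replace(t, dbh_cm=d, dbh_origin="extracted"))
                else:
                    trees.append(dataclasses.replace(t, dbh_cm=None, dbh_origin=None))
            plot2 = uas.with_trees(trees)
            retained = [(t.height_m, t.dbh_cm) for t in plot2.trees if t.dbh_cm is not None]
            if len(retained) >= 5:
                site_model = fit_power_model(*map(np.asarray, zip(*retained)))
            else:
                site_model = regional
            plot2 = impute_missing_dbh(plot2, site_model)
            n_ext = sum(1 for t in plot2.trees if t.dbh_origin == "extracted")
            dbh_log.append(
                {
                    "plot": stem.plot_id,
                    "n_uas": len(plot2),
                    "n_extracted": n_ext,
                    "extraction_rate": n_ext / len(plot2) if len(plot2) else 0.0,
                    "site_beta1": site_model.beta1,
                    "site_beta2": site_model.beta2,
                }
            )
            path = out / f"uasdbh_{stem.plot_id}.csv"
            write_tree_csv(plot2, path)
            uas_with_dbh.append(plot2)
            files.append(path)
        log_path = out / "dbh_log.json"
        log_path.write_text(json.dumps(dbh_log, indent=2))
        files.append(log_path)
        finish_stage("dbh", files)

        # --- match -----------------------------------------------------
        files = []
        rate_rows = []
        err_frames = []
        matches_list = []
        for stem, uas in zip(stem_plots, uas_with_dbh):
            m = match_trees(
                uas, stem,
                max_dist_m=config.match_max_dist_m,
                max_height_err_m=config.match_max_height_err_m,
            )
            matches_list.append(m)
            rates = detection_rates(m, uas, stem)
            for cls, entry in rates.per_class.items():
                rate_rows.append({"plot": stem.plot_id, "class": cls, **entry})
            err = error_summary(m, uas, stem)
            err.insert(0, "plot", stem.plot_id)
            err_frames.append(err)
        rates_path = out / "detection_rates.csv"
        pd.DataFrame(rate_rows).to_csv(rates_path, index=False)
        err_path = out / "error_summary.csv"
        pd.concat(err_frames, ignore_index=True).to_csv(err_path, index=False)
        files += [rates_path, err_path]
        finish_stage("match", files)

        # --- summarize -------------------------------------------------
        rows = []
        for stem, uas, cover_uas in zip(stem_plots, uas_with_dbh, covers_uas):
            s_sm = stand_summary(stem, cover=dissolved_crown_cover(stem))
            s_uas = stand_summary(uas, cover=cover_uas)
            rows.append(
                {
                    "plot": stem.plot_id,
                    "qmd_cm_sm": s_sm.qmd_cm, "qmd_cm_uas": s_uas.qmd_cm,
                    "tph_sm": s_sm.tph, "tph_uas": s_uas.tph,
                    "tph_gt5_sm": s_sm.tph_gt5, "tph_gt5_uas": s_uas.tph_gt5,
                    "ba_m2ha_sm": s_sm.ba_m2ha, "ba_m2ha_uas": s_uas.ba_m2ha,
                    "cover_pct_sm": 100 * s_sm.cover_frac,
                    "cover_pct_uas": 100 * s_uas.cover_frac,
                }
            )
        summary_path = out / "stand_summaries.csv"
        pd.DataFrame(rows).to_csv(summary_path, index=False)
        finish_stage("summarize", [summary_path])

        # --- clumps + openings ----------------------------------------
        stem_long = structure_metrics_long(
            stem_plots, eps_m=config.clump_eps_m,
            grid_m=config.opening_grid_m, band_m=config.opening_band_m,
        )
        uas_long = structure_metrics_long(
            uas_with_dbh, eps_m=config.clump_eps_m,
            grid_m=config.opening_grid_m, band_m=config.opening_band_m,
        )
        stem_long_path = out / "structure_stem.csv"
        uas_long_path = out / "structure_uas.csv"
        stem_long.to_csv(stem_long_path, index=False)
        uas_long.to_csv(uas_long_path, index=False)
        finish_stage("clumps", [stem_long_path, uas_long_path])
        finish_stage("openings", [])

        # --- anova -----------------------------------------------------
        table = compare_structure_metrics(stem_long, uas_long)
        anova_path = out / "anova_table.csv"
        table.to_csv(anova_path, index=False)
        finish_stage("anova", [anova_path])
    except Exception as exc:
        done = manifest["stages"]
        stage = STAGES[len(done)] if len(done) < len(STAGES) else "anova"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_manifest(run_dir: str | Path) -> dict:
    return json.loads((Path(run_dir) / "manifest.json").read_text())
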