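"""End-to-end pipeline: simulate -> soil accounting -> tree accounting ->
moisture models -> ALS tree-C map -> SOC map -> landscape summary.

Every stage records the SHA-256 of its inputs and outputs in
``manifest.json``. On a re-run, a stage whose outputs exist and whose
recorded input hashes still match is skipped, so deleting an intermediate
regenerates only the stages downstream of it.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as bio
from .als import (
    AlsCarbonRegressor,
    cell_metrics,
    exclusion_filter,
    lorey_height,
    predict_raster,
)
from .config import PipelineConfig
from .errors import BorealCarbonError
from .rasters import RasterGrid, read_raster, write_raster
from .records import CarbonPools
from .regression import WetnessCarbonRegressor, loocv
from .soil import total_soc
from .summary import (
    partition_report,
    soc_raster,
    summaries_frame,
    summarize_pools,
    tree_fraction_by_class,
)
from .synthetic import generate_catchment
from .trees import AllometryTable, DEFAULT_ALLOMETRY, impute_heights, plot_tree_carbon


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


class Pipeline:
    """Stage orchestration over an output directory."""

    def __init__(self, config: PipelineConfig, out_dir, seed: Optional[int] = None):
        self.config = config.validate()
        self.seed = config.seed if seed is None else seed
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()
        self.allometry = (
            AllometryTable.from_dict(json.loads(Path(config.allometry_path).read_text()))
            if config.allometry_path
            else DEFAULT_ALLOMETRY
        )

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            m = json.loads(self.manifest_path.read_text())
            if m.get("config_hash") == _config_hash(self.config) and m.get("seed") == self.seed:
                return m
        return {
            "version": __version__,
            "seed": self.seed,
            "config_hash": _config_hash(self.config),
            "stages": {},
        }

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _fresh(self, stage: str, inputs: List[Path], outputs: List[Path]) -> bool:
        rec = self.manifest["stages"].get(stage)
        if rec is None or not all(p.exists() for p in outputs):
            return False
        return all(
            p.exists() and rec["inputs"].get(p.name) == _sha256(p) for p in inputs
        ) and list(rec["outputs"]) == [p.name for p in outputs]

    def _record(self, stage: str, inputs: List[Path], outputs: List[Path]) -> None:
        self.manifest["stages"][stage] = {
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": [p.name for p in outputs],
        }
        self._save_manifest()

    # -- stages -----------------------------------------------------------

    def simulate(self) -> Dict[str, Path]:
        paths = {
            name: self.out / name
            for name in (
                "plots.csv",
                "profiles.csv",
                "trees.csv",
                "als_points.csv",
                "wetness.asc",
            )
        }
        outputs = list(paths.values())
        if self._fresh("simulate", [], outputs):
            return paths
        catchment = generate_catchment(self.config.generator, seed=self.seed, allometry=self.allometry)
        bio.write_table(bio.plots_to_frame(catchment.plots), paths["plots.csv"])
        bio.write_table(bio.profiles_to_frame(catchment.profiles), paths["profiles.csv"])
        bio.write_table(bio.trees_to_frame(catchment.trees), paths["trees.csv"])
        bio.write_table(bio.als_points_to_frame(catchment.als_points), paths["als_points.csv"])
        write_raster(catchment.wetness, paths["wetness.asc"])
        self._record("simulate", [], outputs)
        return paths

    def soilc(self) -> Path:
        src = self.out / "profiles.csv"
        dst = self.out / "soil_pools.csv"
        if self._fresh("soilc", [src], [dst]):
            return dst
        profiles = bio.frame_to_profiles(bio.read_table(src, bio.PROFILES_SCHEMA))
        pools = [total_soc(p) for p in profiles]
        df = pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in pools],
                "organic": [p.organic for p in pools],
                "mineral": [p.mineral for p in pools],
                "total_soc": [p.total_soc for p in pools],
                "is_peat": [p.is_peat for p in pools],
            }
        )
        bio.write_table(df, dst, bio.SOIL_POOLS_SCHEMA)
        self._record("soilc", [src], [dst])
        return dst

    def treec(self) -> Path:
        trees_src = self.out / "trees.csv"
        plots_src = self.out / "plots.csv"
        dst = self.out / "tree_pools.csv"
        if self._fresh("treec", [trees_src, plots_src], [dst]):
            return dst
        trees = bio.frame_to_trees(bio.read_table(trees_src, bio.TREES_SCHEMA))
        plots = bio.frame_to_plots(bio.read_table(plots_src, bio.PLOTS_SCHEMA))
        trees = impute_heights(trees) if trees else []
        by_plot: Dict[str, list] = {}
        for t in trees:
            by_plot.setdefault(t.plot_id, []).append(t)
        rows = []
        for p in plots:
            pools = plot_tree_carbon(
                by_plot.get(p.plot_id, []), p.radius, self.allometry, plot_id=p.plot_id
            )
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "tree_above": pools.tree_above,
                    "tree_below": pools.tree_below,
                    "tree_total": pools.tree_total,
                }
            )
        bio.write_table(pd.DataFrame(rows), dst, bio.TREE_POOLS_SCHEMA)
        self._record("treec", [trees_src, plots_src], [dst])
        return dst

    def _merged_pools(self) -> pd.DataFrame:
        soil = bio.read_table(self.out / "soil_pools.csv", bio.SOIL_POOLS_SCHEMA)
        tree = bio.read_table(self.out / "tree_pools.csv", bio.TREE_POOLS_SCHEMA)
        plots = bio.read_table(self.out / "plots.csv", bio.PLOTS_SCHEMA)
        return soil.merge(tree, on="plot_id").merge(
            plots[["plot_id", "wetness", "moisture_class", "stand_age", "x", "y", "radius"]],
            on="plot_id",
        )

    def fit(self) -> Path:
        inputs = [self.out / n for n in ("soil_pools.csv", "tree_pools.csv", "plots.csv")]
        dst = self.out / "models.json"
        if self._fresh("fit", inputs, [dst]):
            return dst
        df = self._merged_pools()
        x = df["wetness"].to_numpy(float)
        models = {}
        specs = {
            "total_soc": dict(degree=self.config.soc_degree, log_scale=self.config.soc_log_scale),
            "organic": dict(degree=2, log_scale=True),
            "mineral": dict(degree=1, log_scale=False),
            "tree_total": dict(degree=2, log_scale=False),
        }
        for pool, spec in specs.items():
            y = df[pool].to_numpy(float)
            mask = y > 0 if spec["log_scale"] else np.ones_like(y, dtype=bool)
            model = WetnessCarbonRegressor(**spec).fit(x[mask], y[mask])
            model.rmse_loocv_, model.r2_loocv_ = loocv(x[mask], y[mask], **spec)
            models[pool] = model.to_dict()
        dst.write_text(json.dumps(models, indent=2))
        self._record("fit", inputs, [dst])
        return dst

    def _plot_metrics(self) -> pd.DataFrame:
        points = bio.frame_to_als_points(
            bio.read_table(self.out / "als_points.csv", bio.ALS_POINTS_SCHEMA)
        )
        trees = bio.frame_to_trees(bio.read_table(self.out / "trees.csv", bio.TREES_SCHEMA))
        trees = impute_heights(trees) if trees else []
        by_plot: Dict[str, list] = {}
        for t in trees:
            by_plot.setdefault(t.plot_id, []).append(t)
        rows = []
        for pid, heights in points.items():
            m = cell_metrics(heights, self.config.canopy_threshold, cell_id=pid)
            if m.n_points == 0:
                continue
            plot_trees = by_plot.get(pid, [])
            lorey = lorey_height(plot_trees) if plot_trees else 0.0
            rows.append(
                {
                    "plot_id": pid,
                    "p95": m.p95,
                    "hsd": m.hsd,
                    "vr": m.vr,
                    "n_points": m.n_points,
                    "lorey": lorey,
                }
            )
        return pd.DataFrame(rows)

    def map_tree(self) -> Dict[str, Path]:
        inputs = [self.out / n for n in ("als_points.csv", "trees.csv", "tree_pools.csv", "plots.csv")]
        paths = {
            "model": self.out / "als_model.json",
            "raster": self.out / "tree_c_12p5m.asc",
            "exclusions": self.out / "exclusions.csv",
        }
        outputs = list(paths.values())
        if self._fresh("map_tree", inputs, outputs):
            return paths
        metrics = self._plot_metrics()
        tree_pools = bio.read_table(self.out / "tree_pools.csv", bio.TREE_POOLS_SCHEMA)
        merged = metrics.merge(tree_pools, on="plot_id")
        kept, excluded = exclusion_filter(merged, self.config.exclusion_limit)
        model = AlsCarbonRegressor(exponent=self.config.als_exponent).fit(
            kept, kept["tree_total"].to_numpy(float)
        )
        paths["model"].write_text(json.dumps(model.to_dict(), indent=2))
        bio.write_table(excluded, paths["exclusions"])

        # metric rasters on the 12.5 m grid covering the plot layout
        plots = bio.read_table(self.out / "plots.csv", bio.PLOTS_SCHEMA)
        cell = self.config.generator.als_cell_size
        extent_x = plots["x"].max() + self.config.generator.grid_spacing / 2
        extent_y = plots["y"].max() + self.config.generator.grid_spacing / 2
        shape = (int(math.ceil(extent_y / cell)), int(math.ceil(extent_x / cell)))
        origin = (0.0, shape[0] * cell)
        nodata = -9999.0
        grids = {
            k: RasterGrid(np.full(shape, nodata), origin=origin, cell_size=cell, nodata=nodata)
            for k in ("p95", "hsd", "vr")
        }
        located = merged.merge(plots[["plot_id", "x", "y"]], on="plot_id")
        for row in located.itertuples(index=False):
            r, c = grids["p95"].cell_of(row.x, row.y)
            for k in ("p95", "hsd", "vr"):
                grids[k].values[r, c] = getattr(row, k)
        pred, n_clamped = predict_raster(model, grids["p95"], grids["hsd"], grids["vr"])
        write_raster(pred, paths["raster"])
        rec = json.loads(paths["model"].read_text())
        rec["clamped_cells"] = n_clamped
        rec["excluded_plots"] = int(len(excluded))
        paths["model"].write_text(json.dumps(rec, indent=2))
        self._record("map_tree", inputs, outputs)
        return paths

    def map_soc(self) -> Path:
        inputs = [self.out / "models.json", self.out / "wetness.asc"]
        dst = self.out / "soc_2m.asc"
        if self._fresh("map_soc", inputs, [dst]):
            return dst
        models = json.loads((self.out / "models.json").read_text())
        model = WetnessCarbonRegressor.from_dict(models["total_soc"])
        wetness = read_raster(self.out / "wetness.asc")
        write_raster(soc_raster(model, wetness), dst)
        self._record("map_soc", inputs, [dst])
        return dst

    def summarize(self) -> Dict[str, Path]:
        inputs = [self.out / n for n in ("soil_pools.csv", "tree_pools.csv", "plots.csv")]
        paths = {"summary": self.out / "summary.csv", "partition": self.out / "partition.json"}
        outputs = list(paths.values())
        if self._fresh("summarize", inputs, outputs):
            return paths
        df = self._merged_pools()
        summaries = summarize_pools(df)
        bio.write_table(summaries_frame(summaries), paths["summary"])
        report = partition_report(summaries)
        payload = {
            "partition": report.to_dict(),
            "partition_rounded": report.rounded(),
            "tree_share_by_class": tree_fraction_by_class(df),
        }
        paths["partition"].write_text(json.dumps(payload, indent=2))
        self._record("summarize", inputs, outputs)
        return paths

    def run_all(self) -> Dict[str, Path]:
        artifacts: Dict[str, Path] = {}
        artifacts.update(self.simulate())
        artifacts["soil_pools.csv"] = self.soilc()
        artifacts["tree_pools.csv"] = self.treec()
        artifacts["models.json"] = self.fit()
        artifacts.update({f"tree_{k}": v for k, v in self.map_tree().items()})
        artifacts["soc_2m.asc"] = self.map_soc()
        artifacts.update(self.summarize())
        return artifacts


def run_pipeline(config: PipelineConfig, out_dir, seed: Optional[int] = None) -> Dict[str, Path]:
    """Run every stage; returns the artifact paths."""
    return Pipeline(config, out_dir, seed=seed).run_all()
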