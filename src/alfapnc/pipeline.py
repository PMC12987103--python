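"""End-to-end orchestration: simulate → extract → screen → train → map.

Every stage writes its artifacts (CSV/JSON/TIFF) into the run directory
together with a manifest recording the resolved configuration, seeds and
package version, so a run can be reproduced exactly.  The individual
steps are plain functions over in-memory objects; the file layout is a
thin convention on top.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .glcm import GLCMParams, quantization_ranges, tfv_names, tfv_table
from .indices import VI_NAMES, vi_table
from .mapping import PNCMap, TrainedPncModel, map_summary, predict_map, write_map
from .models import MODEL_NAMES, compare_models, make_model, residual_summary
from .raster import read_stack, write_stack, zonal_table
from .scene import (StageData, generate_dataset, layout_from_geojson,
                    layout_to_geojson, write_ground_truth)
from .screening import (assemble_feature_sets, correlate_features, select_tis,
                        select_vis, summarize_tfv_vs_ti)
from .tindex import add_ti_columns, screen_tis, ti_feature_name

log = logging.getLogger(__name__)

_CSV_FMT = "%.10g"


def extract_features(
    stage: StageData, glcm_params: GLCMParams = GLCMParams()
) -> pd.DataFrame:
    """Sample table with band means, 10 VI columns and 48 TFV columns."""
    rois = stage.layout.frame_rois()
    zt = zonal_table(stage.stack, rois).drop(columns=["plot_id"])
    zt = vi_table(zt)
    tt = tfv_table(stage.stack, rois, glcm_params).drop(columns=["plot_id"])
    out = stage.samples.merge(zt, on="sample_id").merge(tt, on="sample_id")
    if len(out) != len(stage.samples):
        raise RuntimeError("feature extraction lost sample rows")
    return out


@dataclass
class ScreeningResult:
    vi_correlations: pd.DataFrame
    tfv_correlations: pd.DataFrame
    ti_catalog: pd.DataFrame
    selected_vis: list[str]
    selected_tis: list[tuple[str, str, str]]
    feature_sets: dict[str, list[str]]
    features: pd.DataFrame  # table augmented with selected TI columns
    ti_summary: dict[str, float] | None

    def manifest(self) -> dict:
        cat = self.ti_catalog
        best = {}
        for fam, t1, t2 in self.selected_tis:
            row = cat[(cat["family"] == fam) & (cat["t1"] == t1) & (cat["t2"] == t2)]
            best[fam] = {"t1": t1, "t2": t2,
                         "r": float(row["r"].iloc[0]), "p": float(row["p"].iloc[0])}
        vis = self.vi_correlations.set_index("feature")
        return {
            "selected_vis": {
                v: {"r": float(vis.loc[v, "r"]), "p": float(vis.loc[v, "p"])}
                for v in self.selected_vis
            },
            "selected_tis": best,
            "feature_sets": self.feature_sets,
            "ti_summary": self.ti_summary,
        }


def screen_features(
    features: pd.DataFrame,
    threshold: float = 0.5,
    top_vis: int = 3,
) -> ScreeningResult:
    """Variable filtering: top VIs, best TI per family, fused group."""
    vi_corr = correlate_features(features, list(VI_NAMES))
    tfv_cols = [c for c in tfv_names() if c in features.columns]
    tfv_corr = correlate_features(features, tfv_cols)
    catalog = screen_tis(features)
    sel_vis = select_vis(vi_corr, threshold=threshold, top=top_vis)
    sel_tis = select_tis(catalog, threshold=threshold)
    ti_cols = [ti_feature_name(*t) for t in sel_tis]
    feature_sets = assemble_feature_sets(sel_vis, ti_cols)
    features_aug = add_ti_columns(features, sel_tis)
    summary = None
    if sel_tis:
        best_rows = []
        for fam, t1, t2 in sel_tis:
            row = catalog[(catalog["family"] == fam) & (catalog["t1"] == t1)
                          & (catalog["t2"] == t2)].iloc[0]
            best_rows.append(row)
        summary = summarize_tfv_vs_ti(tfv_corr, pd.DataFrame(best_rows))
    return ScreeningResult(
        vi_correlations=vi_corr, tfv_correlations=tfv_corr, ti_catalog=catalog,
        selected_vis=sel_vis, selected_tis=sel_tis, feature_sets=feature_sets,
        features=features_aug, ti_summary=summary,
    )


def train_final_model(
    screening: ScreeningResult,
    stage_data: StageData,
    glcm_params: GLCMParams,
    model_name: str = "XGB",
    feature_set: str = "VIs+TIs",
    seed: int = 0,
) -> TrainedPncModel:
    """Fit the mapping model on all samples of one stage."""
    features = screening.feature_sets[feature_set]
    if not features:
        raise ValueError(f"feature set {feature_set!r} is empty")
    table = screening.features
    X = table[features].to_numpy(dtype=np.float64)
    y = table["PNC"].to_numpy(dtype=np.float64)
    model = make_model(model_name, random_state=seed)
    model.fit(X, y)
    return TrainedPncModel(
        model=model, feature_names=features, glcm_params=glcm_params,
        quant_ranges=quantization_ranges(stage_data.stack),
        stage=stage_data.stage, model_name=model_name,
        feature_set=feature_set, seed=seed,
    )


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": cfg.seed,
        "config": cfg.to_dict(), "stages": {},
    }
    glcm_params = cfg.glcm_params()
    dataset = generate_dataset(cfg.scene_config(), seed=cfg.seed)
    first = True
    for stage, sd in dataset.items():
        log.info("stage %s: simulate", stage)
        arts: dict = {}
        scene_path = outdir / f"scene_{stage}.tif"
        write_stack(sd.stack, scene_path)
        arts["scene"] = scene_path.name
        if first:
            layout_to_geojson(sd.layout, outdir / "layout.geojson")
            manifest["layout"] = "layout.geojson"
            first = False
        gt_path = outdir / f"ground_truth_{stage}.csv"
        _write_csv(sd.ground_truth, gt_path)
        arts["ground_truth"] = gt_path.name

        log.info("stage %s: extract features", stage)
        features = extract_features(sd, glcm_params)
        log.info("stage %s: screen variables", stage)
        scr = screen_features(
            features,
            threshold=cfg.screening["threshold"],
            top_vis=cfg.screening["top_vis"],
        )
        _write_csv(scr.features, outdir / f"features_{stage}.csv")
        _write_csv(scr.vi_correlations, outdir / f"vi_correlations_{stage}.csv")
        _write_csv(scr.tfv_correlations, outdir / f"tfv_correlations_{stage}.csv")
        _write_csv(scr.ti_catalog, outdir / f"ti_catalog_{stage}.csv")
        _write_json(scr.manifest(), outdir / f"selection_{stage}.json")
        arts.update({
            "features": f"features_{stage}.csv",
            "selection": f"selection_{stage}.json",
            "ti_catalog": f"ti_catalog_{stage}.csv",
        })

        log.info("stage %s: train and compare models", stage)
        usable_sets = {k: v for k, v in scr.feature_sets.items() if v}
        summary, reports = compare_models(
            scr.features, usable_sets,
            model_names=tuple(cfg.models["names"]),
            seed=cfg.seed, stage=stage,
            repeats=int(cfg.models["repeats"]),
            train_frac=float(cfg.models["train_frac"]),
            grid_search=bool(cfg.models["grid_search"]),
        )
        _write_csv(summary, outdir / f"model_reports_{stage}.csv")
        res_rows = []
        for (model, fs), rep in reports.items():
            rs = residual_summary(rep)
            rs.insert(0, "feature_set", fs)
            rs.insert(0, "model", model)
            res_rows.append(rs)
        _write_csv(pd.concat(res_rows, ignore_index=True),
                   outdir / f"residuals_{stage}.csv")
        arts["model_reports"] = f"model_reports_{stage}.csv"
        arts["n_model_reports"] = len(reports)

        if cfg.mapping.get("enabled", True):
            fs_name = cfg.mapping["feature_set"]
            if scr.feature_sets.get(fs_name):
                log.info("stage %s: invert PNC map", stage)
                trained = train_final_model(
                    scr, sd, glcm_params,
                    model_name=cfg.mapping["model"],
                    feature_set=fs_name, seed=cfg.seed,
                )
                pnc_map = predict_map(trained, sd.stack)
                write_map(pnc_map, outdir / f"pnc_map_{stage}.tif")
                ms = map_summary(pnc_map, sd.layout)
                ms = ms.merge(sd.ground_truth[["plot_id", "PNC"]], on="plot_id")
                _write_csv(ms, outdir / f"map_summary_{stage}.csv")
                lo, hi = pnc_map.range()
                arts["pnc_map"] = f"pnc_map_{stage}.tif"
                arts["map_range"] = [lo, hi]
            else:
                log.warning("stage %s: mapping skipped (empty feature set %r)",
                            stage, fs_name)
        manifest["stages"][stage] = arts
    _write_json(manifest, outdir / "manifest.json")
    return outdir
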