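"""Per-pixel PNC map inversion.

A trained fused-feature model is applied across a full band stack:
vegetation-index and texture-feature rasters are computed per pixel with
the same GLCM settings — and, critically, the same per-band quantization
range — as during training, the selected texture-index rasters are
formed from them, and the model predicts a nitrogen-content value at
every valid pixel.  Pixels with any missing feature are masked out.

Note that extracting ROI-mean features and predicting once is not the
same as averaging the per-pixel predictions unless the model is linear;
the map is the per-pixel route, the sample table the ROI-mean route.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .glcm import GLCMParams, texture_image
from .indices import VI_NAMES, vi_image
from .raster import BandStack, zonal_mean_image
from .tindex import TI_FUNCTIONS, parse_ti_feature_name

log = logging.getLogger(__name__)


class FeatureContractError(ValueError):
    """The stack cannot provide a feature the model was trained on."""


@dataclass
class TrainedPncModel:
    """A fitted regressor plus everything needed to apply it to rasters."""

    model: object
    feature_names: list[str]
    glcm_params: GLCMParams
    quant_ranges: dict[str, tuple[float, float]]
    stage: str | None = None
    model_name: str = ""
    feature_set: str = ""
    seed: int | None = None

    def provenance(self) -> dict:
        return {
            "model": self.model_name or type(self.model).__name__,
            "feature_set": self.feature_set,
            "features": list(self.feature_names),
            "stage": self.stage,
            "seed": self.seed,
            "glcm": {
                "window": self.glcm_params.window,
                "levels": self.glcm_params.levels,
                "distance": self.glcm_params.distance,
                "directions": list(self.glcm_params.directions),
            },
            "quant_ranges": {k: list(v) for k, v in self.quant_ranges.items()},
        }


@dataclass
class PNCMap:
    """Raster of predicted plant nitrogen content (% dry mass)."""

    values: np.ndarray
    mask: np.ndarray
    provenance: dict

    def range(self) -> tuple[float, float]:
        vals = self.values[self.mask]
        return float(vals.min()), float(vals.max())


def _tfv_name_parts(name: str) -> tuple[str, str] | None:
    parts = name.split("_", 1)
    from .glcm import FEATURES
    from .raster import BAND_NAMES

    if len(parts) == 2 and parts[0] in BAND_NAMES and parts[1] in FEATURES:
        return parts[0], parts[1]
    return None


def _feature_rasters(
    trained: TrainedPncModel, stack: BandStack
) -> dict[str, np.ndarray]:
    """Compute exactly the rasters the model's features require."""
    needed_tfvs: set[str] = set()
    plan: list[tuple[str, str]] = []  # (kind, name)
    for name in trained.feature_names:
        ti = parse_ti_feature_name(name)
        if name in VI_NAMES:
            plan.append(("vi", name))
        elif ti is not None:
            plan.append(("ti", name))
            needed_tfvs.update(ti[1:])
        elif _tfv_name_parts(name) is not None:
            plan.append(("tfv", name))
            needed_tfvs.add(name)
        else:
            raise FeatureContractError(f"cannot compute feature {name!r} from a band stack")
    tfv_imgs: dict[str, np.ndarray] = {}
    by_band: dict[str, list[str]] = {}
    for tfv in needed_tfvs:
        band, feat = _tfv_name_parts(tfv)
        by_band.setdefault(band, []).append(feat)
    for band, feats in sorted(by_band.items()):
        vrange = trained.quant_ranges.get(band)
        imgs = texture_image(stack.band(band), trained.glcm_params, vrange=vrange)
        for feat in feats:
            tfv_imgs[f"{band}_{feat}"] = imgs[feat]
    out: dict[str, np.ndarray] = {}
    for kind, name in plan:
        if kind == "vi":
            out[name] = vi_image(stack, name)
        elif kind == "tfv":
            out[name] = tfv_imgs[name]
        else:
            family, t1, t2 = parse_ti_feature_name(name)
            out[name] = TI_FUNCTIONS[family](tfv_imgs[t1], tfv_imgs[t2])
    return out


def predict_map(trained: TrainedPncModel, stack: BandStack) -> PNCMap:
    """Apply a trained model pixelwise, producing a PNC raster."""
    rasters = _feature_rasters(trained, stack)
    H, W = stack.shape
    feat_stack = np.stack([rasters[n] for n in trained.feature_names], axis=0)
    valid = stack.mask & np.isfinite(feat_stack).all(axis=0)
    values = np.full((H, W), np.nan, dtype=np.float32)
    if valid.any():
        X = feat_stack[:, valid].T
        values[valid] = trained.model.predict(X).astype(np.float32)
    else:
        log.warning("no valid pixels to predict")
    return PNCMap(values=values, mask=valid, provenance=trained.provenance())


def map_summary(pnc_map: PNCMap, layout) -> pd.DataFrame:
    """Per-plot mean predicted PNC (verification aid against ground truth)."""
    img = np.where(pnc_map.mask, pnc_map.values.astype(np.float64), np.nan)
    rows = []
    for roi in layout.plot_rois():
        rows.append({"plot_id": roi.plot_id or roi.id,
                     "pnc_pred_mean": zonal_mean_image(img, roi)})
    return pd.DataFrame(rows)


def write_map(pnc_map: PNCMap, path: str | Path) -> None:
    """Single-band float32 TIFF with provenance in the description tag."""
    data = pnc_map.values.copy()
    data[~pnc_map.mask] = np.nan
    tifffile.imwrite(str(path), data, description=json.dumps(pnc_map.provenance))


def read_map(path: str | Path) -> PNCMap:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    prov = json.loads(desc) if desc else {}
    return PNCMap(values=arr, mask=np.isfinite(arr), provenance=prov)
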