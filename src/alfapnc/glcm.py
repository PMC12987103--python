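"""Windowed gray-level co-occurrence (GLCM) texture features.

Implements the texture-feature extraction used throughout the pipeline:
each band is globally quantized to ``levels`` gray levels by linear
min–max scaling, a sliding window (default 9×9) is centered on every
pixel, and a symmetric co-occurrence matrix is tallied per direction
(0°, 45°, 90°, 135° at the given pixel distance).  Eight Haralick-style
features are computed per direction and then averaged over the four
directions:

====  ==========================================================
mean  μ = Σ_ij i · P(i, j)
var   Σ_ij (i − μ)² · P(i, j)
hom   Σ_ij P(i, j) / (1 + (i − j)²)          (homogeneity)
con   Σ_ij (i − j)² · P(i, j)                (contrast)
diss  Σ_ij |i − j| · P(i, j)                 (dissimilarity)
ent   −Σ_ij P·ln P  with 0·ln 0 := 0         (entropy)
corr  Σ_ij (i − μx)(j − μy) P / (σx σy)      (correlation)
sm    Σ_ij P(i, j)²                          (second moment)
====  ==========================================================

Conventions: the co-occurrence matrix is symmetric (each pixel pair is
counted in both orders); windows are truncated at raster edges (only
pairs with both pixels inside the window and the image count — no
padding); a zero-variance window has corr := 1.0 (a constant patch is
perfectly self-similar); the feature value is assigned to the window's
center pixel.  Masked pixels are excluded from pairs, and a window with
no valid pair in a direction contributes nothing to that pixel's
direction average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .raster import BandStack, ROI, zonal_mean_image

log = logging.getLogger(__name__)

#: Feature order used everywhere (column naming, arrays).
FEATURES: tuple[str, ...] = ("mean", "var", "hom", "con", "diss", "ent", "corr", "sm")

#: Direction → (row, col) unit offset.
DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


class EmptyInputError(ValueError):
    """Raised when a raster has no unmasked pixels."""


@dataclass(frozen=True)
class GLCMParams:
    """Texture-extraction settings.

    window: odd sliding-window edge length in pixels (9 balances canopy
    detail against cost); levels: number of gray levels after global
    quantization (64 keeps texture while bounding the matrix); distance:
    pixel offset between co-occurring pixels (1 = adjacent); directions:
    offsets in degrees, averaged to suppress row-orientation anisotropy.
    """

    window: int = 9
    levels: int = 64
    distance: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.directions or any(d not in DIRECTION_OFFSETS for d in self.directions):
            raise ValueError(f"directions must be among {tuple(DIRECTION_OFFSETS)}")


def quantize(
    band: np.ndarray,
    levels: int,
    vrange: tuple[float, float] | None = None,
) -> np.ndarray:
    """Quantize a reflectance band to integer gray levels 0..levels-1.

    Linear min–max scaling over the whole (unmasked) raster; a constant
    raster maps to all zeros.  Masked (non-finite) pixels become -1.
    ``vrange`` overrides the scaling range (used when applying a model to
    a new scene with the training scene's quantization).
    """
    band = np.asarray(band, dtype=np.float64)
    valid = np.isfinite(band)
    if not valid.any():
        raise EmptyInputError("all pixels are masked; nothing to quantize")
    if vrange is None:
        lo, hi = float(band[valid].min()), float(band[valid].max())
    else:
        lo, hi = map(float, vrange)
    q = np.full(band.shape, -1, dtype=np.int32)
    if hi <= lo:
        q[valid] = 0
        return q
    scaled = (band[valid] - lo) / (hi - lo) * levels
    q[valid] = np.clip(scaled.astype(np.int64), 0, levels - 1).astype(np.int32)
    return q


def glcm_matrix(
    window_pixels: np.ndarray,
    direction: int,
    distance: int = 1,
    levels: int = 64,
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix of one quantized window.

    ``window_pixels`` is a 2-D integer array (−1 = masked).  Both pixels
    of a pair must lie inside the array and be unmasked.  Returns a
    ``levels × levels`` matrix summing to 1, or all zeros when the window
    has no valid pair.
    """
    q = np.asarray(window_pixels)
    dy, dx = DIRECTION_OFFSETS[direction]
    dy, dx = dy * distance, dx * distance
    h, w = q.shape
    P = np.zeros((levels, levels), dtype=np.float64)
    for r in range(h):
        r2 = r + dy
        if r2 < 0 or r2 >= h:
            continue
        for c in range(w):
            c2 = c + dx
            if c2 < 0 or c2 >= w:
                continue
            a, b = q[r, c], q[r2, c2]
            if a < 0 or b < 0:
                continue
            P[a, b] += 1.0
            P[b, a] += 1.0
    total = P.sum()
    if total > 0:
        P /= total
    return P


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Eight Haralick-style features of a normalized co-occurrence matrix."""
    total = P.sum()
    if total <= 0:
        return {f: float("nan") for f in FEATURES}
    levels = P.shape[0]
    i = np.arange(levels, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    mean = float((ii * P).sum())
    var = float((((ii - mean) ** 2) * P).sum())
    hom = float((P / (1.0 + diff**2)).sum())
    con = float((diff**2 * P).sum())
    diss = float((np.abs(diff) * P).sum())
    nz = P > 0
    ent = float(-(P[nz] * np.log(P[nz])).sum())
    sm = float((P**2).sum())
    sxy = np.sqrt(var_x * var_y)
    if sxy > 0:
        corr = float((((ii - mu_x) * (jj - mu_y)) * P).sum() / sxy)
    else:
        corr = 1.0
    return {
        "mean": mean, "var": var, "hom": hom, "con": con,
        "diss": diss, "ent": ent, "corr": corr, "sm": sm,
    }


@njit(cache=True)
def _accumulate_direction(q, half, dy, dx, levels, compute, out, ndir, counts, touched):  # pragma: no cover - numba
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            if not compute[r, c]:
                continue
            rlo = max(r - half, 0)
            rhi = min(r + half, H - 1)
            clo = max(c - half, 0)
            chi = min(c + half, W - 1)
            ntouch = 0
            npairs = 0
            for i in range(rlo, rhi + 1):
                i2 = i + dy
                if i2 < rlo or i2 > rhi:
                    continue
                for j in range(clo, chi + 1):
                    j2 = j + dx
                    if j2 < clo or j2 > chi:
                        continue
                    a = q[i, j]
                    b = q[i2, j2]
                    if a < 0 or b < 0:
                        continue
                    npairs += 1
                    k1 = a * levels + b
                    k2 = b * levels + a
                    if counts[k1] == 0:
                        touched[ntouch] = k1
                        ntouch += 1
                    counts[k1] += 1
                    if k2 != k1:
                        if counts[k2] == 0:
                            touched[ntouch] = k2
                            ntouch += 1
                        counts[k2] += 1
                    else:
                        counts[k2] += 1
            if npairs == 0:
                continue
            total = 2.0 * npairs
            mu = 0.0
            for t in range(ntouch):
                k = touched[t]
                p = counts[k] / total
                a = k // levels
                mu += a * p
            var = 0.0
            hom = 0.0
            con = 0.0
            diss = 0.0
            ent = 0.0
            sm = 0.0
            cov = 0.0
            for t in range(ntouch):
                k = touched[t]
                p = counts[k] / total
                a = k // levels
                b = k % levels
                d = a - b
                var += (a - mu) * (a - mu) * p
                hom += p / (1.0 + d * d)
                con += d * d * p
                if d < 0:
                    diss += -d * p
                else:
                    diss += d * p
                ent += -p * np.log(p)
                sm += p * p
                cov += (a - mu) * (b - mu) * p
                counts[k] = 0
            if var > 0.0:
                corr = cov / var
            else:
                corr = 1.0
            out[0, r, c] += mu
            out[1, r, c] += var
            out[2, r, c] += hom
            out[3, r, c] += con
            out[4, r, c] += diss
            out[5, r, c] += ent
            out[6, r, c] += corr
            out[7, r, c] += sm
            ndir[r, c] += 1


def texture_image(
    band: np.ndarray,
    params: GLCMParams = GLCMParams(),
    centers: np.ndarray | None = None,
    vrange: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Eight texture-feature images of one band.

    Each pixel receives the direction-averaged window features.  When
    ``centers`` (boolean array) is given, only those pixels are computed
    (others are NaN) — window contents still come from the full raster.
    ``vrange`` fixes the quantization range (see :func:`quantize`).
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2:
        raise ValueError("band must be 2-D")
    if min(band.shape) < params.window:
        raise ValueError(
            f"band shape {band.shape} smaller than window {params.window}"
        )
    q = quantize(band, params.levels, vrange=vrange)
    valid = q >= 0
    if centers is None:
        compute = valid
    else:
        compute = np.asarray(centers, dtype=bool) & valid
    half = params.window // 2
    H, W = band.shape
    out = np.zeros((8, H, W), dtype=np.float64)
    ndir = np.zeros((H, W), dtype=np.int32)
    counts = np.zeros(params.levels * params.levels, dtype=np.int64)
    touched = np.zeros(2 * params.window * params.window, dtype=np.int64)
    for direction in params.directions:
        dy, dx = DIRECTION_OFFSETS[direction]
        _accumulate_direction(
            q, half, dy * params.distance, dx * params.distance,
            params.levels, compute, out, ndir, counts, touched,
        )
    with np.errstate(invalid="ignore"):
        result = out / np.where(ndir > 0, ndir, 1)
    result[:, ndir == 0] = np.nan
    return {feat: result[k] for k, feat in enumerate(FEATURES)}


def tfv_names(bands: Sequence[str] = ("B", "G", "R", "RE1", "RE2", "NIR")) -> list[str]:
    """The 48 texture-feature column names in band-major order."""
    return [f"{b}_{f}" for b in bands for f in FEATURES]


def tfv_table(
    stack: BandStack,
    rois: Sequence[ROI],
    params: GLCMParams = GLCMParams(),
    vranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-ROI zonal means of the 48 texture features (6 bands × 8).

    Texture images are evaluated only at pixels covered by the ROIs;
    column names follow the ``band_feature`` scheme (``B_mean`` …
    ``NIR_sm``).  ROIs with no computable pixel get NaN features.
    """
    shape = stack.shape
    union = np.zeros(shape, dtype=bool)
    footprints = []
    for roi in rois:
        fp = roi.footprint(shape) & stack.mask
        footprints.append(fp)
        union |= fp
    rows = [{"sample_id": roi.id, "plot_id": roi.plot_id} for roi in rois]
    for bname in stack.band_names:
        vrange = None if vranges is None else vranges.get(bname)
        feats = texture_image(stack.band(bname), params, centers=union, vrange=vrange)
        for fname, img in feats.items():
            col = f"{bname}_{fname}"
            for k, fp in enumerate(footprints):
                vals = img[fp]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    log.warning("ROI %s: no valid pixels for %s", rois[k].id, col)
                    rows[k][col] = float("nan")
                else:
                    rows[k][col] = float(vals.mean())
    return pd.DataFrame(rows)


def quantization_ranges(stack: BandStack) -> dict[str, tuple[float, float]]:
    """Global per-band min–max used for quantization (stored as provenance)."""
    out = {}
    for name in stack.band_names:
        b = stack.band(name)
        v = b[np.isfinite(b)]
        if v.size == 0:
            raise EmptyInputError(f"band {name} fully masked")
        out[name] = (float(v.min()), float(v.max()))
    return out
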