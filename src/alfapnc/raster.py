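"""Multi-band raster and ROI handling.

A :class:`BandStack` holds the six reflectance bands of the multispectral
camera (blue, green, red, two red-edge bands, near-infrared) as a single
float32 array plus a validity mask.  Stacks round-trip through multi-band
TIFF files with band names, an affine transform and the nodata convention
recorded in a JSON ``ImageDescription`` tag.  Regions of interest are
shapely polygons in pixel coordinates; a pixel belongs to an ROI iff its
center lies inside the polygon (half-open convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon, box, shape as shapely_shape
from shapely import contains_xy

log = logging.getLogger(__name__)

#: Canonical band order; center wavelengths in nm.
BAND_NAMES: tuple[str, ...] = ("B", "G", "R", "RE1", "RE2", "NIR")
BAND_WAVELENGTHS: dict[str, int] = {
    "B": 450, "G": 555, "R": 660, "RE1": 720, "RE2": 750, "NIR": 840,
}

IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class RasterFormatError(ValueError):
    """Raised when a raster file does not match the expected 6-band layout."""


class EmptyROIError(ValueError):
    """Raised when an ROI covers no unmasked pixel."""


@dataclass
class BandStack:
    """Six coregistered reflectance bands on a common pixel grid.

    Parameters
    ----------
    data:
        Array of shape ``(6, H, W)``, float32, reflectance nominally in
        ``[0, 1]``.
    mask:
        Boolean ``(H, W)`` array, ``True`` where pixels are valid.
    transform:
        Affine coefficients ``(a, b, c, d, e, f)`` mapping pixel
        ``(col, row)`` to world coordinates; identity by default (the
        pipeline works in pixel coordinates).
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    transform: tuple = IDENTITY_TRANSFORM
    band_names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.band_names):
            raise RasterFormatError(
                f"expected ({len(self.band_names)}, H, W) data, got {self.data.shape}"
            )
        if tuple(self.band_names) != BAND_NAMES:
            raise RasterFormatError(f"band names must be {BAND_NAMES}")
        if self.mask is None:
            self.mask = np.isfinite(self.data).all(axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise RasterFormatError("mask shape does not match band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a float array with NaN at masked pixels."""
        i = self.band_names.index(name)
        out = self.data[i].astype(np.float64)
        out[~self.mask] = np.nan
        return out

    def bands(self) -> dict[str, np.ndarray]:
        return {name: self.band(name) for name in self.band_names}


def write_stack(stack: BandStack, path: str | Path) -> None:
    """Write a stack as a 6-band float32 TIFF with JSON metadata."""
    data = stack.data.copy()
    data[:, ~stack.mask] = np.nan
    meta = {
        "band_names": list(stack.band_names),
        "transform": list(stack.transform),
        "nodata": "nan",
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_stack(path: str | Path, scale_factor: float | None = None) -> BandStack:
    """Read a 6-band TIFF written by :func:`write_stack` (or compatible).

    Integer rasters are rescaled to reflectance by ``scale_factor``
    (e.g. 1/10000 for common surface-reflectance products).
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise RasterFormatError(f"{path}: expected a 3-D band stack, got {arr.shape}")
    # accept (H, W, 6) interleaved layout as well
    if arr.shape[0] != 6 and arr.shape[-1] == 6:
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] != 6:
        raise RasterFormatError(
            f"{path}: expected 6 bands, found {arr.shape[0]}"
        )
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if np.issubdtype(arr.dtype, np.integer):
        if scale_factor is None:
            raise RasterFormatError(
                f"{path}: integer raster requires a scale_factor"
            )
        arr = arr.astype(np.float32) * scale_factor
    arr = arr.astype(np.float32)
    mask = np.isfinite(arr).all(axis=0)
    transform = tuple(meta.get("transform", IDENTITY_TRANSFORM))
    names = tuple(meta.get("band_names", BAND_NAMES))
    return BandStack(arr, mask=mask, transform=transform, band_names=names)


@dataclass
class ROI:
    """A polygonal region of interest in pixel coordinates.

    ``geometry`` uses x = column, y = row; rectangles may be given as
    ``(row0, col0, row1, col1)`` half-open bounds via :meth:`from_rect`.
    """

    id: str
    geometry: Polygon
    plot_id: str | None = None

    @classmethod
    def from_rect(cls, id: str, rect: Sequence[float], plot_id: str | None = None) -> "ROI":
        r0, c0, r1, c1 = rect
        return cls(id=id, geometry=box(c0, r0, c1, r1), plot_id=plot_id)

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (H, W) array of pixels whose centers fall inside."""
        h, w = shape
        minx, miny, maxx, maxy = self.geometry.bounds
        c0 = max(int(np.floor(minx)), 0)
        r0 = max(int(np.floor(miny)), 0)
        c1 = min(int(np.ceil(maxx)) + 1, w)
        r1 = min(int(np.ceil(maxy)) + 1, h)
        out = np.zeros(shape, dtype=bool)
        if c1 <= c0 or r1 <= r0:
            return out
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = contains_xy(self.geometry, cols + 0.5, rows + 0.5)
        out[r0:r1, c0:c1] = inside
        return out


def zonal_mean(stack: BandStack, roi: ROI) -> dict[str, float]:
    """Arithmetic mean of unmasked pixels per band within an ROI."""
    fp = roi.footprint(stack.shape) & stack.mask
    if not fp.any():
        raise EmptyROIError(f"ROI {roi.id!r} covers no unmasked pixel")
    return {
        name: float(stack.data[i][fp].mean())
        for i, name in enumerate(stack.band_names)
    }


def zonal_mean_image(image: np.ndarray, roi: ROI) -> float:
    """Mean of finite values of a single 2-D image within an ROI."""
    fp = roi.footprint(image.shape)
    vals = image[fp]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def zonal_table(stack: BandStack, rois: Sequence[ROI]) -> "pd.DataFrame":
    """Per-ROI band means as a table with columns sample_id, B..NIR."""
    import pandas as pd

    rows = []
    for roi in rois:
        rec: dict = {"sample_id": roi.id, "plot_id": roi.plot_id}
        rec.update(zonal_mean(stack, roi))
        rows.append(rec)
    return pd.DataFrame(rows)


def rois_to_geojson(rois: Sequence[ROI], path: str | Path) -> None:
    features = []
    for roi in rois:
        features.append({
            "type": "Feature",
            "properties": {"id": roi.id, "plot_id": roi.plot_id},
            "geometry": roi.geometry.__geo_interface__,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def rois_from_geojson(path: str | Path) -> list[ROI]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        out.append(ROI(
            id=str(props.get("id")),
            geometry=shapely_shape(feat["geometry"]),
            plot_id=props.get("plot_id"),
        ))
    return out
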