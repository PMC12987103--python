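"""Multispectral vegetation indices.

Ten indices computed from the six camera bands (B, G, R, RE1, RE2, NIR).
Each formula is a pure function of band reflectances and works on scalars
or arrays alike.  Near-zero denominators yield NaN (a missing value),
never an exception, so per-pixel index images degrade gracefully.

Note: this MCARI variant uses the NIR / red-edge-1 band pair rather than
the classical green/red/700 nm set, and MSR/RERDVI carry a square-root
denominator; both are implemented exactly as defined here.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_EPS = 1e-9


class SchemaError(ValueError):
    """A required band or feature column is missing."""


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.where(np.abs(den) < _EPS, np.nan, num / np.where(np.abs(den) < _EPS, 1.0, den))
    return out if out.ndim else float(out)


def _safe_sqrt(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, np.sqrt(np.where(x > 0, x, 1.0)), np.nan)
    return out


def _ndvi(b):
    return _safe_div(b["NIR"] - b["R"], b["NIR"] + b["R"])


def _evi(b):
    return _safe_div(2.5 * (b["NIR"] - b["R"]), b["NIR"] + 6.0 * b["R"] - 7.5 * b["B"] + 1.0)


def _rerdvi(b):
    return _safe_div(b["NIR"] - b["RE1"], _safe_sqrt(b["NIR"] + b["RE1"]))


def _msr(b):
    ratio = _safe_div(b["NIR"], b["R"])
    return _safe_div(ratio - 1.0, _safe_sqrt(ratio + 1.0))


def _sipi(b):
    return _safe_div(b["NIR"] - b["B"], b["NIR"] - b["R"])


def _mcari(b):
    return ((b["NIR"] - b["RE1"]) - 0.2 * (b["NIR"] - b["R"])) * _safe_div(b["NIR"], b["RE1"])


def _reosavi(b):
    return 1.16 * _safe_div(b["NIR"] - b["RE1"], b["NIR"] + b["RE1"] + 0.16)


def _nni(b):
    return _safe_div(b["NIR"], b["NIR"] + b["RE1"] + b["G"])


def _ngi(b):
    return _safe_div(b["G"], b["NIR"] + b["G"] + b["RE1"])


def _gndvi(b):
    return _safe_div(b["NIR"] - b["G"], b["NIR"] + b["G"])


VI_FUNCTIONS: dict[str, Callable[[Mapping[str, np.ndarray]], np.ndarray]] = {
    "NDVI": _ndvi,
    "EVI": _evi,
    "RERDVI": _rerdvi,
    "MSR": _msr,
    "SIPI": _sipi,
    "MCARI": _mcari,
    "REOSAVI": _reosavi,
    "NNI": _nni,
    "NGI": _ngi,
    "GNDVI": _gndvi,
}

VI_NAMES: tuple[str, ...] = tuple(VI_FUNCTIONS)


def compute_vi(name: str, bands: Mapping[str, float | np.ndarray]):
    """Compute one vegetation index from band reflectances.

    ``bands`` maps band names to scalars or equally-shaped arrays.
    Returns NaN where a denominator is within 1e-9 of zero.
    """
    try:
        fn = VI_FUNCTIONS[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}; known: {VI_NAMES}")
    return fn(bands)


def vi_image(stack, name: str) -> np.ndarray:
    """Per-pixel index image from a BandStack (NaN outside the mask)."""
    return np.asarray(compute_vi(name, stack.bands()), dtype=np.float64)


def vi_table(zonal: pd.DataFrame, names: tuple[str, ...] = VI_NAMES) -> pd.DataFrame:
    """Append vegetation-index columns to a per-sample band-mean table."""
    required = {"B", "G", "R", "RE1", "RE2", "NIR"}
    missing = required - set(zonal.columns)
    if missing:
        raise SchemaError(f"zonal table lacks band columns: {sorted(missing)}")
    out = zonal.copy()
    bands = {k: zonal[k].to_numpy(dtype=np.float64) for k in required}
    for name in names:
        out[name] = compute_vi(name, bands)
    n_bad = int(out[list(names)].isna().any(axis=1).sum())
    if n_bad:
        log.warning("%d rows with undefined vegetation indices", n_bad)
    return out
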