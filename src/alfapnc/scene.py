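"""Synthetic multispectral field scenes with known nitrogen ground truth.

Emulates the study design the pipeline targets: a 4-block randomized
field of 16 plots (four nitrogen levels N0–N3, each once per block),
three sampling frames per plot (48 samples per growth stage), and a
6-band reflectance raster per stage in which both the plot-mean spectra
and the within-plot texture carry a planted, noisy relationship with
plant nitrogen content (PNC).

PNC ground truth per stage is drawn from a nitrogen-level-shifted normal
whose pooled mean/SD match the stage defaults (branching 3.31 ± 0.26 %,
budding 2.75 ± 0.33 %, initial flowering 2.64 ± 0.27 %), truncated to
the stage's observed range.  Leaf/stem components (LNC, SNC, LDM, SDM)
are generated so that PNC is exactly their mass-weighted mean.

Rasters are built as plot-mean reflectance (linear in PNC per band,
negative in the red/red-edge-1, positive in the NIR) plus a spatially
correlated texture field whose amplitude also tracks PNC, a sinusoidal
row pattern, and white noise, clipped to [0, 1].  Spectral and textural
noise channels are independent, so vegetation indices and texture
indices carry complementary information about PNC — the property the
feature-fusion comparison exploits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster import BAND_NAMES, BandStack, ROI

log = logging.getLogger(__name__)

N_LEVELS: tuple[str, ...] = ("N0", "N1", "N2", "N3")
STAGES: tuple[str, ...] = ("branching", "budding", "initial_flowering")

#: Per-stage PNC distribution targets: (mean %, SD %, min %, max %).
STAGE_PNC: dict[str, tuple[float, float, float, float]] = {
    "branching": (3.31, 0.26, 2.82, 4.16),
    "budding": (2.75, 0.33, 1.80, 3.39),
    "initial_flowering": (2.64, 0.27, 1.99, 3.14),
}

#: Canopy baseline reflectance per band at the stage-mean PNC.
DEFAULT_BAND_BASE: dict[str, float] = {
    "B": 0.045, "G": 0.090, "R": 0.050, "RE1": 0.160, "RE2": 0.320, "NIR": 0.450,
}

#: Reflectance change per percentage point of PNC: nitrogen-rich canopies
#: absorb more red/red-edge-1 light and scatter more NIR.
DEFAULT_BAND_COEF: dict[str, float] = {
    "B": -0.004, "G": -0.008, "R": -0.015, "RE1": -0.020, "RE2": 0.020, "NIR": 0.050,
}

#: Bare-soil background reflectance (brighter in the visible, flat shape).
SOIL_BASE: dict[str, float] = {
    "B": 0.10, "G": 0.14, "R": 0.18, "RE1": 0.21, "RE2": 0.23, "NIR": 0.26,
}


def compute_pnc(lnc: float, ldm: float, snc: float, sdm: float) -> float:
    """Plant nitrogen content as the dry-mass-weighted mean of leaf and
    stem nitrogen concentrations: (LNC·LDM + SNC·SDM)/(LDM + SDM), in %.
    """
    if ldm < 0 or sdm < 0:
        raise ValueError("dry masses must be non-negative")
    total = ldm + sdm
    if total <= 0:
        raise ValueError("at least one of LDM, SDM must be positive")
    return (lnc * ldm + snc * sdm) / total


@dataclass(frozen=True)
class PlotSpec:
    plot_id: str
    block: int
    n_level: str
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass
class FieldLayout:
    """16 plots in 4 blocks plus square sampling frames per plot."""

    plots: list[PlotSpec]
    sampling_frames: dict[str, list[tuple[int, int, int, int]]]
    shape: tuple[int, int]

    def plot(self, plot_id: str) -> PlotSpec:
        return next(p for p in self.plots if p.plot_id == plot_id)

    def frame_rois(self) -> list[ROI]:
        out = []
        for plot in self.plots:
            for k, rect in enumerate(self.sampling_frames[plot.plot_id], start=1):
                out.append(ROI.from_rect(f"{plot.plot_id}_F{k}", rect, plot.plot_id))
        return out

    def plot_rois(self) -> list[ROI]:
        return [ROI.from_rect(p.plot_id, p.rect, p.plot_id) for p in self.plots]


@dataclass(frozen=True)
class SceneParams:
    """Stage-level generator settings.

    ``pnc_*`` control the ground-truth distribution (percent dry mass);
    ``band_base``/``band_coef`` the PNC→reflectance link;
    ``spectral_noise_ratio`` sizes plot-level spectral noise relative to
    the PNC signal (4/3 puts single-band correlations near |r| ≈ 0.6);
    texture parameters control the spatially correlated within-plot
    field (correlation length in pixels, amplitude in reflectance units
    in the NIR, PNC loading and noise loading of the amplitude), the
    sinusoidal row pattern, and per-pixel white noise.
    """

    stage: str = "branching"
    pnc_mean: float = 3.31
    pnc_sd: float = 0.26
    pnc_min: float = 2.82
    pnc_max: float = 4.16
    band_base: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_BASE))
    band_coef: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_COEF))
    spectral_noise_ratio: float = 4.0 / 3.0
    texture_corr_length: float = 1.5
    texture_amplitude: float = 0.030
    texture_pnc_coef: float = 0.60
    texture_noise_coef: float = 0.50
    row_period: float = 12.0
    row_amplitude: float = 0.008
    noise_sd: float = 0.010
    shape: tuple[int, int] = (200, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pnc_sd <= 0:
            raise ValueError("pnc_sd must be positive")
        if min(self.shape) < 64:
            raise ValueError("raster size must be at least 64x64")

    @classmethod
    def for_stage(cls, stage: str, seed: int = 0, **overrides) -> "SceneParams":
        mean, sd, lo, hi = STAGE_PNC[stage]
        return cls(stage=stage, pnc_mean=mean, pnc_sd=sd, pnc_min=lo,
                   pnc_max=hi, seed=seed, **overrides)


@dataclass(frozen=True)
class GroundTruthRecord:
    plot_id: str
    stage: str
    LNC: float
    SNC: float
    LDM: float
    SDM: float
    PNC: float


def generate_layout(
    seed: int,
    shape: tuple[int, int] = (200, 200),
    plot_size: int = 40,
    margin: int = 8,
    frames_per_plot: int = 3,
    frame_size: int = 11,
) -> FieldLayout:
    """Randomized-block field layout: 4×4 grid of plots, blocks = rows.

    Nitrogen levels are shuffled independently within each block with
    the given seed; each plot receives ``frames_per_plot`` square
    sampling frames placed along the plot diagonal.
    """
    need = 4 * plot_size + 5 * margin
    if shape[0] < need or shape[1] < need:
        raise ValueError(f"shape {shape} too small for 4x4 plots of {plot_size}px")
    rng = np.random.default_rng(seed)
    plots: list[PlotSpec] = []
    frames: dict[str, list[tuple[int, int, int, int]]] = {}
    half = frame_size // 2
    fracs = np.linspace(0.2, 0.8, frames_per_plot)
    pid = 0
    for block in range(4):
        levels = list(rng.permutation(np.array(N_LEVELS)))
        r0 = margin + block * (plot_size + margin)
        for col in range(4):
            pid += 1
            c0 = margin + col * (plot_size + margin)
            plot_id = f"P{pid:02d}"
            plots.append(PlotSpec(
                plot_id=plot_id, block=block + 1, n_level=str(levels[col]),
                rect=(r0, c0, r0 + plot_size, c0 + plot_size),
            ))
            frames[plot_id] = []
            for f in fracs:
                cr = r0 + int(round(plot_size * f))
                cc = c0 + int(round(plot_size * f))
                frames[plot_id].append((cr - half, cc - half, cr + half + 1, cc + half + 1))
    return FieldLayout(plots=plots, sampling_frames=frames, shape=shape)


def _ground_truth(layout: FieldLayout, params: SceneParams, rng) -> list[GroundTruthRecord]:
    # nitrogen-level offsets: pooled variance = within^2 + d^2 * 1.25
    d = 0.6 * params.pnc_sd
    within = params.pnc_sd * np.sqrt(1.0 - 1.25 * 0.36)
    records = []
    for plot in layout.plots:
        idx = N_LEVELS.index(plot.n_level)
        pnc = params.pnc_mean + d * (idx - 1.5) + within * rng.standard_normal()
        pnc = float(np.clip(pnc, params.pnc_min, params.pnc_max))
        ldm = float(max(rng.normal(25.0, 5.0), 5.0))
        sdm = float(max(rng.normal(30.0, 6.0), 5.0))
        snc = pnc * float(rng.uniform(0.55, 0.75))
        lnc = (pnc * (ldm + sdm) - snc * sdm) / ldm
        records.append(GroundTruthRecord(
            plot_id=plot.plot_id, stage=params.stage,
            LNC=lnc, SNC=snc, LDM=ldm, SDM=sdm,
            PNC=compute_pnc(lnc, ldm, snc, sdm),
        ))
    return records


def generate_stage(
    layout: FieldLayout,
    params: SceneParams,
) -> tuple[BandStack, list[GroundTruthRecord]]:
    """One stage's 6-band reflectance raster plus per-plot ground truth."""
    rng = np.random.default_rng(params.seed)
    records = _ground_truth(layout, params, rng)
    pnc_by_plot = {r.plot_id: r.PNC for r in records}

    # plot-level spectral noise, independent of the texture channel
    spec_noise = {
        p.plot_id: {
            b: rng.standard_normal() * params.spectral_noise_ratio
            * abs(params.band_coef[b]) * params.pnc_sd
            for b in BAND_NAMES
        }
        for p in layout.plots
    }
    # plot-level texture amplitude: loads on PNC plus independent noise
    tex_amp = {}
    for p in layout.plots:
        z = (pnc_by_plot[p.plot_id] - params.pnc_mean) / params.pnc_sd
        scale = 1.0 + params.texture_pnc_coef * z \
            + params.texture_noise_coef * rng.standard_normal()
        tex_amp[p.plot_id] = params.texture_amplitude * max(scale, 0.2)

    H, W = params.shape
    cols = np.arange(W, dtype=np.float64)
    row_pattern = params.row_amplitude * np.sin(2.0 * np.pi * cols / params.row_period)
    nir_base = params.band_base["NIR"]
    data = np.empty((len(BAND_NAMES), H, W), dtype=np.float32)
    n_clipped = 0
    for bi, b in enumerate(BAND_NAMES):
        fld = rng.standard_normal((H, W))
        if params.texture_corr_length > 0:
            fld = gaussian_filter(fld, params.texture_corr_length)
        sd = fld.std()
        if sd > 0:
            fld = fld / sd
        noise = rng.standard_normal((H, W)) * params.noise_sd
        band_scale = params.band_base[b] / nir_base
        img = np.full((H, W), SOIL_BASE[b], dtype=np.float64)
        img += fld * 0.3 * params.texture_amplitude * band_scale
        for p in layout.plots:
            r0, c0, r1, c1 = p.rect
            mean_b = (
                params.band_base[b]
                + params.band_coef[b] * (pnc_by_plot[p.plot_id] - params.pnc_mean)
                + spec_noise[p.plot_id][b]
            )
            img[r0:r1, c0:c1] = mean_b + fld[r0:r1, c0:c1] * tex_amp[p.plot_id] * band_scale
        img += row_pattern[None, :]
        img += noise
        n_clipped += int(((img < 0) | (img > 1)).sum())
        data[bi] = np.clip(img, 0.0, 1.0, out=img).astype(np.float32)
    if n_clipped:
        log.warning("clipped %d out-of-range reflectance pixels to [0, 1]", n_clipped)
    stack = BandStack(data, mask=np.ones((H, W), dtype=bool))
    return stack, records


@dataclass
class StageData:
    stage: str
    stack: BandStack
    layout: FieldLayout
    ground_truth: pd.DataFrame
    samples: pd.DataFrame  # one row per sampling frame


def ground_truth_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"plot_id": r.plot_id, "stage": r.stage, "LNC": r.LNC, "SNC": r.SNC,
          "LDM": r.LDM, "SDM": r.SDM, "PNC": r.PNC} for r in records]
    )


def _stage_seed(seed: int, index: int) -> int:
    return int((seed + 7919 * (index + 1)) % 2**31)


def generate_dataset(
    config: Mapping | None = None,
    seed: int = 0,
) -> dict[str, StageData]:
    """Generate every configured stage (default: all three).

    ``config`` may carry ``stages`` (names), ``shape`` and per-stage
    SceneParams overrides under ``params``.  The field layout is shared
    across stages; each stage uses a sub-seed derived from the global
    seed by a fixed offset.  The per-stage sample table has one row per
    sampling frame (16 plots × 3 frames = 48), inheriting the plot's
    ground truth, ready for feature extraction.
    """
    config = dict(config or {})
    stages = list(config.get("stages", STAGES))
    if not 1 <= len(stages) <= 3:
        raise ValueError("config must name 1-3 stages")
    shape = tuple(config.get("shape", (200, 200)))
    overrides = dict(config.get("params", {}))
    layout = generate_layout(seed, shape=shape)
    out: dict[str, StageData] = {}
    for i, stage in enumerate(stages):
        params = SceneParams.for_stage(
            stage, seed=_stage_seed(seed, i), shape=shape, **overrides
        )
        stack, records = generate_stage(layout, params)
        gt = ground_truth_frame(records)
        rows = []
        for plot in layout.plots:
            rec = next(r for r in records if r.plot_id == plot.plot_id)
            for k in range(len(layout.sampling_frames[plot.plot_id])):
                rows.append({
                    "sample_id": f"{plot.plot_id}_F{k + 1}",
                    "plot_id": plot.plot_id,
                    "stage": stage,
                    "block": plot.block,
                    "n_level": plot.n_level,
                    "LNC": rec.LNC, "SNC": rec.SNC,
                    "LDM": rec.LDM, "SDM": rec.SDM, "PNC": rec.PNC,
                })
        out[stage] = StageData(
            stage=stage, stack=stack, layout=layout,
            ground_truth=gt, samples=pd.DataFrame(rows),
        )
    return out


def planted_tfv_table(
    seed: int,
    n: int = 48,
    effect_r: float = 0.6,
    family: str = "NDTI",
    pair: tuple[str, str] = ("NIR_mean", "B_mean"),
) -> tuple[pd.DataFrame, tuple[str, str, str]]:
    """A 48-column texture-feature table with one planted index signal.

    The chosen pair is constructed so that the family's index of
    (t1, t2) is linear in PNC plus noise with population correlation
    ``effect_r``; the remaining 46 columns are independent positive
    noise.  Used to verify that the 2304-candidate screen recovers a
    known signal at the study's sample size.
    """
    from .glcm import tfv_names

    rng = np.random.default_rng(seed)
    mean, sd, lo, hi = STAGE_PNC["branching"]
    pnc = mean + sd * rng.standard_normal(n)
    z = (pnc - mean) / sd
    s = effect_r * z + np.sqrt(1.0 - effect_r**2) * rng.standard_normal(n)
    v = 0.15 * np.clip(s, -3.0, 3.0)
    # real texture features are strongly correlated within a band; a
    # per-band latent factor reproduces that dependence structure
    band_factor = {b: rng.standard_normal(n) for b in BAND_NAMES}
    data: dict[str, np.ndarray] = {}
    for name in tfv_names():
        band = name.split("_", 1)[0]
        base = rng.uniform(0.5, 5.0)
        col = base * (1.0 + 0.12 * band_factor[band]
                      + 0.08 * rng.standard_normal(n))
        data[name] = np.maximum(col, 0.05)
    # the planted pair shares a common-mode noise factor that the pairwise
    # index cancels — the mechanism that makes indices outperform raw
    # features — so the pair itself carries the clean signal while pairs
    # involving only one planted column stay attenuated
    t1_name, t2_name = pair
    shared = 1.0 + 0.12 * rng.standard_normal(n)
    b1 = float(rng.uniform(1.0, 3.0))
    b2 = float(rng.uniform(1.0, 3.0))
    data[t1_name] = b1 * shared * (1.0 + v) * (1.0 + 0.02 * rng.standard_normal(n))
    data[t2_name] = b2 * shared * (1.0 - v) * (1.0 + 0.02 * rng.standard_normal(n))
    df = pd.DataFrame(data)
    df.insert(0, "PNC", pnc)
    return df, (family, t1_name, t2_name)


# ---------------------------------------------------------------------------
# serialization

def write_ground_truth(records: Sequence[GroundTruthRecord], path: str | Path) -> None:
    ground_truth_frame(records).to_csv(
        path, index=False,
        columns=["plot_id", "stage", "LNC", "SNC", "LDM", "SDM", "PNC"],
        float_format="%.6f",
    )


def layout_to_geojson(layout: FieldLayout, path: str | Path) -> None:
    def rect_coords(rect):
        r0, c0, r1, c1 = rect
        return [[[c0, r0], [c1, r0], [c1, r1], [c0, r1], [c0, r0]]]

    features = []
    for p in layout.plots:
        features.append({
            "type": "Feature",
            "properties": {"kind": "plot", "plot_id": p.plot_id,
                           "block": p.block, "n_level": p.n_level},
            "geometry": {"type": "Polygon", "coordinates": rect_coords(p.rect)},
        })
        for k, rect in enumerate(layout.sampling_frames[p.plot_id], start=1):
            features.append({
                "type": "Feature",
                "properties": {"kind": "frame", "plot_id": p.plot_id,
                               "frame_id": f"{p.plot_id}_F{k}"},
                "geometry": {"type": "Polygon", "coordinates": rect_coords(rect)},
            })
    fc = {"type": "FeatureCollection",
          "properties": {"shape": list(layout.shape)},
          "features": features}
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


def layout_from_geojson(path: str | Path) -> FieldLayout:
    with open(path) as fh:
        fc = json.load(fh)
    plots: list[PlotSpec] = []
    frames: dict[str, list[tuple[int, int, int, int]]] = {}

    def coords_rect(geom):
        ring = np.asarray(geom["coordinates"][0])
        c0, r0 = ring.min(axis=0)
        c1, r1 = ring.max(axis=0)
        return (int(r0), int(c0), int(r1), int(c1))

    for feat in fc["features"]:
        props = feat["properties"]
        if props["kind"] == "plot":
            plots.append(PlotSpec(
                plot_id=props["plot_id"], block=int(props["block"]),
                n_level=props["n_level"], rect=coords_rect(feat["geometry"]),
            ))
            frames.setdefault(props["plot_id"], [])
        else:
            frames.setdefault(props["plot_id"], []).append(coords_rect(feat["geometry"]))
    shape = tuple(fc.get("properties", {}).get("shape", (200, 200)))
    return FieldLayout(plots=plots, sampling_frames=frames, shape=shape)
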