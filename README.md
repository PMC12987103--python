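# alfapnc

Estimation of plant nitrogen content (PNC) in alfalfa from UAV-style
multispectral imagery, built around feature fusion of spectral
vegetation indices (VIs) and gray-level co-occurrence texture indices
(TIs). The package is aimed at agricultural remote-sensing researchers
who want a tested, reproducible implementation of this analysis —
runnable end to end on synthetic scenes that emulate a randomized-block
nitrogen trial, or on their own 6-band reflectance rasters.

## The analysis

**Ground truth.** PNC is the nitrogen concentration of the stem–leaf
composite, the dry-mass-weighted mean of leaf and stem nitrogen:

    PNC = (LNC·LDM + SNC·SDM) / (LDM + SDM)        [% dry mass]

**Spectral features.** Ten vegetation indices (NDVI, EVI, RERDVI, MSR,
SIPI, MCARI, REOSAVI, NNI, NGI, GNDVI) are computed per pixel from the
six camera bands — blue 450, green 555, red 660, red-edge 720/750 and
NIR 840 nm — and zonally averaged over each sampling frame.

**Texture features.** Each band is quantized to 64 gray levels and a
9×9 sliding-window co-occurrence matrix (distance 1, symmetric) yields
eight Haralick-style statistics (mean, var, hom, con, diss, ent, corr,
sm) averaged over the 0°/45°/90°/135° directions: 6 bands × 8 features
= 48 texture feature values (TFVs) per sample.

**Texture indices.** Any ordered pair (T1, T2) of the 48 TFVs forms

    NDTI = (T1 − T2)/(T1 + T2),  RTI = T1/T2,  RDTI = (T1 − T2)/√(T1 + T2)

giving 48² = 2304 candidates per family. Candidates are screened by
Pearson correlation with PNC (exact t-transform p-values); the best
per family with |r| > 0.5 joins the model inputs, alongside the top
three VIs with |r| > 0.5.

**Models.** Four regressors — random forest (5 trees, depth 3), RBF
support-vector regression (C = 100, ε = 0.1), a two-hidden-layer
perceptron, and gradient boosting (5 trees, depth 2, η = 0.4) — are
compared on three input groups (VIs, TIs, VIs+TIs) with ten repeated
2/3–1/3 random splits, scored by validation R², RMSE and MAE. The
fitted fused-feature model is finally applied per pixel to invert a
PNC map.

The synthetic generator reproduces the trial design: 16 plots (four
nitrogen levels in four randomized blocks), three sampling frames per
plot (48 samples per growth stage), stage PNC distributions of
3.31 ± 0.26 % (branching), 2.75 ± 0.33 % (budding) and 2.64 ± 0.27 %
(initial flowering), and rasters whose plot-mean spectra and
within-plot texture both carry noisy planted PNC signals.

## Worked example

```python
from alfapnc import make_config, run_pipeline
cfg = make_config({"seed": 42, "outdir": "runs/demo",
                   "scene": {"stages": ["branching"]}})
run_pipeline(cfg)
```

or, from the shell, `alfapnc all --seed 42 --outdir runs/demo`. On the
seed-42 branching scene this selects NNI (r = 0.77), REOSAVI (0.71) and
RERDVI (0.69) as VIs and NDTI(RE1_mean, RE2_diss) (−0.88),
RDTI(B_mean, RE2_diss) (−0.85) and RTI(RE2_diss, RE1_mean) (0.88) as
TIs, and writes `model_reports_branching.csv`:

```
feature_set model  validation_r2_mean  validation_rmse_mean  validation_mae_mean
        VIs   XGB               0.451                 0.213                0.177
        TIs   XGB               0.636                 0.176                0.144
    VIs+TIs   RFR               0.772                 0.138                0.107
    VIs+TIs   XGB               0.747                 0.147                0.119
```

(validation metrics, means over the ten splits; RMSE/MAE in PNC
percentage points). The fused groups outperform both single-source
groups for every model on this seed. The per-pixel inversion
`pnc_map_branching.tif` spans 2.98–3.77 % PNC and its plot means
correlate with the generated ground truth at r = 0.94
(`map_summary_branching.csv`).

Each run directory contains the resolved configuration, seed, package
version and every intermediate artifact (scenes as 6-band TIFF, layout
GeoJSON, feature tables, the full 2304-candidate correlation catalogs,
model reports, residual summaries and the PNC maps); reruns with the
same configuration and seed are byte-identical.

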