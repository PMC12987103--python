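# Methods

This note documents the models, conventions and design choices behind
`alfapnc`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ground truth and the synthetic trial

Plant nitrogen content is the dry-mass-weighted mean of leaf and stem
nitrogen concentrations, PNC = (LNC·LDM + SNC·SDM)/(LDM + SDM), in
percent of dry mass. The synthetic generator draws per-plot PNC from a
nitrogen-level-shifted normal: level offsets are 0.6·σ·(k − 1.5) for
levels N0–N3 (k = 0…3), and the within-level SD is chosen so the pooled
variance matches the stage target (offset variance 1.25·(0.6σ)² plus
within-level variance equals σ²). Draws are truncated by clipping to
the stage's observed min–max range; the induced mean shift is ≈0.01·σ,
far below the sampling error of a 48-sample stage. Stage defaults
(mean ± SD, range): branching 3.31 ± 0.26 [2.82, 4.16], budding
2.75 ± 0.33 [1.80, 3.39], initial flowering 2.64 ± 0.27 [1.99, 3.14] %.
Leaf/stem components are generated backwards from PNC: dry masses are
truncated normals (LDM ~ N(25, 5) g, SDM ~ N(30, 6) g, floors at 5 g),
stem nitrogen is a uniform 55–75 % fraction of PNC, and LNC solves the
weighted-mean identity, so the identity holds exactly by construction.

The field layout is a 4×4 grid of 40-px plots with 8-px isolation
margins on a 200×200 grid, blocks = rows, nitrogen levels permuted
independently within each block. How 48 observations arise from 16
plots is not specified by the trial description the generator emulates;
we place **three 11×11-px sampling frames per plot** along the plot
diagonal (16 × 3 = 48), a stand-in consistent with diagonal five-point
sampling. Frames inherit their plot's ground truth, so the 48 samples
contain 16 independent PNC values — tests that compare sample means to
stage targets use 16 as the effective n.

## Scene model

Reflectance per band is built as

  plot mean + correlated texture field + row pattern + white noise,

clipped to [0, 1] (clipping is logged). Plot means are linear in PNC
with band coefficients negative in the visible/red-edge-1 and positive
in red-edge-2/NIR (canopy chlorophyll absorbs red, scatters NIR), plus
a per-plot, per-band spectral noise term scaled to 4/3 of the signal
SD, which puts single-band plot-level correlations with PNC near
|r| ≈ 0.6. The texture field is Gaussian-filtered white noise
(correlation length 1.5 px) scaled per plot by an amplitude that loads
on standardized PNC (coefficient 0.6) and on independent noise (0.5),
giving an amplitude–PNC correlation of ≈0.77 before screening; after
the 2304-candidate selection the screened texture-index correlations
land in the 0.6–0.9 band. The spectral and textural noise channels are
drawn independently so the two feature families carry partially
complementary information. Soil background uses a bright, spectrally
flat profile; a sinusoidal row pattern (period 12 px) adds the
anisotropy that direction-averaging is meant to suppress.

What the generator does **not** emulate: radiative transfer, canopy
gaps and shadows, orthomosaicking artifacts, view/illumination
geometry, or any soil–water process. Consequently, passing tests show
that the pipeline's statistics and protocol behave correctly under
known signal/noise structure — not that the specific indices selected
here would be selected on real imagery.

## Texture features

Bands are quantized **globally** (per raster, not per window) to 64
levels by linear min–max scaling, so gray levels are comparable across
ROIs; a constant band maps to level 0. Co-occurrence matrices are
symmetric (each pixel pair counted in both orders), distance 1, with
offsets 0° = (0, +1), 45° = (−1, +1), 90° = (−1, 0), 135° = (−1, −1) in
(row, col) convention. Windows are truncated at raster edges — only
pairs with both pixels inside the window and the image count; no
padding is invented. The eight features use the standard definitions
(entropy in nats with 0·ln 0 := 0); the eight features are computed
per direction and the **features are averaged** over directions (not
the matrices). A zero-variance window takes corr := 1.0 — a constant
patch is perfectly self-similar — and the same convention is applied in
the test oracle. The feature value is assigned to the window's center
pixel. For mapping, a trained model stores its scene's per-band
quantization ranges and reuses them on new scenes, keeping gray levels
comparable between training and inversion.

The reference software whose texture output this emulates does not
publish its exact formulas or direction handling; the Haralick-style
definitions above are the documented contract, and the implementation
is verified against a brute-force pair-enumeration oracle and against
scikit-image's co-occurrence matrices (whose diagonal angle convention
is mirrored; the symmetric matrix makes offset sign irrelevant).

## Texture indices and screening

All 48² = 2304 ordered TFV pairs are enumerated per family — this
honors the stated combination count, which only the ordered-pairs
reading reproduces — but self-pairs yield constant series (NDTI ≡ 0,
RTI ≡ 1) and are excluded from ranking. RDTI's printed formula is
ambiguous; by analogy with the renormalized-difference vegetation
index it is read as (T1 − T2)/√(T1 + T2), with non-positive sums
yielding missing values. Correlations are pairwise-complete; candidates
with fewer than 10 complete rows are dropped; ties in |r| break
lexicographically by (family, t1, t2) for reproducibility. No
multiple-testing correction is applied to the screen — the permutation
test in the suite demonstrates the resulting selection effect (the
best of 2304 null candidates is far from zero) as a diagnostic.

Selection rules: up to three VIs with |r| > 0.5, ranked by |r|; the
single best candidate per TI family with |r| > 0.5; the fused group is
their concatenation, VIs first. Screening uses the same 48-sample
stage table as model fitting.

## Models and evaluation

Fixed hyperparameters are the defaults (RFR: 5 trees, depth 3; SVR:
RBF, C = 100, ε = 0.1; BPNN: hidden layers (16, 8), relu, adam,
lr 0.001, L2 α = 0.001, tol 1e-4, patience 10; XGB: 5 trees, depth 2,
lr 0.4, L1 α = 0.1, L2 λ = 1.0). Hidden sizes and the XGB
regularization weights are not pinned by the protocol being mirrored
and are exposed in the configuration. An optional grid-search mode
(4-fold CV over small documented grids) can override the fixed values.
SVR and BPNN standardize inputs and target inside the estimator
pipeline, so folds only ever see training statistics; tree models take
raw features. Evaluation draws ten 2/3–1/3 random splits (fully
random, matching the mirrored protocol; plot-stratified splitting is a
deliberate non-default because frames from one plot on both sides of a
split constitute pseudo-replication), refits per split, and reports
means and SDs; per-repeat seeds derive from the master seed by fixed
offsets. Residual summaries report per-repeat median, IQR and
1.5·IQR outliers.

## Numerical conventions

Denominators within 1e-9 of zero yield missing values (never raster
exceptions); missing values propagate pairwise-complete into
correlations and mask pixels in maps. Pearson p-values use the exact
t transform with n − 2 degrees of freedom, two-sided. Zonal statistics
use the pixel-center-in-polygon rule. Reflectance is float32 in [0, 1];
integer rasters require an explicit scale factor at read time.

## Problem sizes

Default scenes are 200×200 px — large enough for 16 plots with
isolation margins and for 9×9 texture windows well inside each 11×11
sampling frame, small enough that a full stage (scene, 48-TFV
extraction, 3×2304 screen, 12 model evaluations, per-pixel map)
completes in seconds. Stochastic suite checks use 50–100 regenerated
datasets.

## Known limitations

- The cheap texture model (separable filtered noise) makes GLCM window
  means track plot reflectance closely; texture indices built on
  `*_mean` features therefore partially duplicate the spectral channel.
  One consequence, measured honestly by the suite's protocol-stability
  test: the fused feature group beats *both* single groups for the
  boosting model in only about half of regenerated datasets, because
  the TI group alone already spans most of the available information.
- With 16 validation samples and validation R² around 0.55–0.70, the
  split-to-split SD of R̂² is of order 0.1; a SD below 0.02 is not
  attainable at this sample size and signal strength, and the
  corresponding stability assertion in the acceptance suite documents
  this expectedly-failing mirror of the published stability claim.
- Screened texture-index correlations are inflated by the 2304-way
  selection effect (quantified by the permutation diagnostic); they are
  not unbiased estimates of the planted effect.
- No reprojection, radiometric calibration or mosaicking: rasters are
  taken as already-calibrated reflectance on a common grid.
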