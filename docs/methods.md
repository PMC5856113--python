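# Methods

## Pipeline

`grasspix` implements a supervised pixel-wise segmentation pipeline for
8-bit RGB UAV orthomosaics over six arid-land cover classes (1 buffel
grass, 2 soil/road, 3 bushes, 4 shadow, 5 dry vegetation, 6 spinifex):

1. **Labelling.** Class masks are derived from flood-filled labelling
   images by exact colour equality against a six-colour palette
   (`H(x,y) = a` iff the pixel equals `F(R,G,B)` of class `a`, else 0).
2. **Features.** Every pixel is described by hue, saturation, value and
   seven windowed-variance channels: var(hue) at w ∈ {3, 15}, var(sat)
   at w ∈ {3, 15}, var(gray) at w ∈ {3, 7, 15}. The asymmetry (no
   variance of the value channel; grayscale texture instead) is part of
   the feature definition and is kept as such.
3. **Training.** Labelled rows are pooled across images in row-major
   scan order, split 75/25 (seeded, unstratified; train size
   = ⌊0.75·n⌋), and fit with a multiclass softmax gradient-boosted tree
   ensemble. k-fold cross-validation (k = 10) and an optional grid
   search report generalisation accuracy.
4. **Prediction.** An orthomosaic is partitioned exactly into 400-px
   tiles (edge tiles smaller, processed as-is); each tile's pixels are
   classified by ensemble argmax (ties to the lowest class code) and
   exported as single-band label GeoTIFF plus palette render.
5. **Validation.** Confusion matrix (rows = labelled), per-class
   precision/recall, **arithmetic-mean f-score**, support, a mean row,
   and pairwise error decomposition.

## Conventions and numerical choices

* **Scales.** Hue in degrees [0, 360) with hue 0 for achromatic pixels;
  saturation/value in [0, 1]; grayscale is BT.601 luma
  (0.299 R + 0.587 G + 0.114 B) on [0, 255]. Variance is computed on
  each channel's native scale; tree ensembles are scale-equivariant per
  feature, so no normalisation is applied. Hue's circular discontinuity
  at 0/360° is *not* special-cased in the variance filter; a red-hued
  textured surface straddling the wrap would read as exaggerated hue
  variance. None of the six default classes sits near the wrap.
* **Variance filter.** Population variance via box-mean of squares
  minus squared box-mean, computed with `scipy.ndimage.uniform_filter`.
  Borders use symmetric reflection by default (`replicate` available);
  w = 1 is identically zero. Results below 64·ε·max(1, E[X²]) — the
  filter's own float64 round-off floor — are clamped to exactly 0, so
  constant inputs give identically zero output.
* **Exact colour matching.** No tolerance in mask encoding; JPEG
  labelling images are rejected outright since lossy compression
  perturbs flood-filled colours.
* **Boosting.** XGBoost with `tree_method="exact"` and one thread:
  split thresholds fall midway between training values (so a cleanly
  separable gap generalises to points inside the gap) and runs are
  bit-reproducible given the seed. Defaults: 100 estimators, learning
  rate 0.1, max depth 3. The default tuning grid is
  {50, 100, 200} × {0.01, 0.1, 0.3} × {3, 5, 7}; grid-search ties break
  towards fewest trees, then shallowest depth, then lowest rate.
* **Cross-validation target.** The workflow description this package
  follows nominally cross-validates on the *test* partition; since that
  re-uses held-out data, the default here cross-validates on the
  training partition, with `cv_on_test: true` available to replicate
  the literal procedure. Accuracy is plain fraction correct; fold
  spread is the population standard deviation.
* **Report rounding.** Percentages are displayed at 2 decimals with
  half-up rounding; the mean row averages the *rounded* per-class
  values (standard report-table arithmetic — full-precision averaging
  can differ in the last digit). Full precision is retained on the
  report object. Classes with an empty row or column report 0 with a
  warning instead of raising.
* **f-score.** Arithmetic mean of precision and recall by definition
  here; harmonic F1 is available via `f_score="harmonic"` for
  comparisons with other tools but is never the default.
* **GeoTIFF.** Georeferencing is carried by the ModelPixelScale,
  ModelTiepoint and GeoKeyDirectory tags (north-up affine, pixel-area
  raster, EPSG code), written and parsed directly through tifffile.
  KML sidecars contain footprints only.

## Synthetic scenes

Real survey imagery of this kind is rarely shareable, so testing runs
on generated scenes: a soil background with seeded elliptical blobs of
the other five classes. Each class has an HSV prototype — base colour,
independent per-pixel Gaussian jitter on H/S/V, and a value-channel
*texture amplitude* that drives the local variance the window filters
respond to. Blob pixel budgets follow the prototype mixture weights
exactly (the final blob of a class is trimmed in scan order). Default
prototypes deliberately mirror the real confusion structure: buffel
(hue 85°) and spinifex (70°) adjacent, bushes (95°, darker, most
textured) overlapping buffel, soil and shadow highly distinct.

What the generator does *not* emulate: spatial autocorrelation beyond
blob shape, illumination gradients, shadows cast by geometry, mixed
pixels at boundaries, sensor noise/vignetting, or seasonal senescence
gradients. Passing the synthetic end-to-end checks therefore shows the
pipeline machinery is sound and that texture features carry the
intended signal — not that the published field accuracies transfer to
new imagery.

The texture-contrast experiment uses two classes identical in colour
(value-noise amplitudes 0.02 vs 0.06). For those amplitudes the optimal
single-pixel (colour-only) classifier has a theoretical accuracy
ceiling of ≈ 0.74, while the w×w variance estimates (χ² concentration,
variance ratio 9) are nearly disjoint — so an HSV-only model should
hover near that ceiling and the full 10-feature model should clear
0.9, which is exactly what the acceptance checks assert.

## Problem sizes

The default experiment scale — four 256×256 training scenes at 5%
labelling coverage (~13k samples), two held-out scenes (~131k pixels),
texture contrast at 192×192 — keeps a full reproduction run around a
minute on a single CPU while leaving every class with thousands of
evaluation pixels.

## Limitations

* Per-pixel classification only: no spatial regularisation or object
  reasoning; speckle in ambiguous regions (e.g. bushes) is expected.
* Six fixed class codes; remapping to other taxonomies means editing
  the palette and class tables.
* The GeoTIFF codec covers north-up affine rasters with a single EPSG
  code — no rotated transforms, no full CRS citation geokeys.
* Circular hue is treated linearly (see above).
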