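# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Image model and segmentation chain

The unit of analysis is a processed ("for presentation") MLO mammogram:
a 2-D non-negative integer matrix (default 12-bit) whose intensities have
been non-linearly transformed by the vendor for display, plus the
acquisition parameters stored in the header.  All images are converted to
bright-is-dense polarity on load (MONOCHROME1-style storage is
complemented) and oriented so the breast abuts the left edge with the
pectoral muscle in the upper-left.  Orientation is decided from the pixel
mass of the two image halves rather than the laterality flag, making the
operation idempotent.

The segmentation chain is:

1. **Cropping.**  Rows/columns in which essentially no pixel exceeds 2%
   of the intensity range are trimmed.  If the crop would discard more
   than half of the signal it is skipped with a warning.
2. **Breast masking.**  The grayscale image is mapped through a
   pseudo-colour map ("Reds" by default, chosen so tissue renders reddish
   and air near-white) and the NTSC Q chroma channel is thresholded at
   Q > 0.  After small-object removal and hole filling, the largest
   connected component touching the chest-wall edge is kept and
   regularised by its convex hull, which smooths the skin line.  On the
   phantom suite this attains Dice ≈ 0.98 against truth.
3. **Pectoral removal (MLO only).**  Pixels above the Otsu cut of the
   upper-left breast window are reduced to the component touching both
   the top and left edges; a straight line is fitted to its lower-right
   boundary and everything above-left of the line is moved to the
   pectoral mask.  A safety valve refuses any "pectoral" claiming more
   than half the breast.  CC views are a no-op.
4. **CLAHE.**  Adaptive histogram equalisation on an 8×8 tile grid with
   clip limit 0.003 of the range.  The clip limit is deliberately small:
   it lifts dim structure without flattening the intra-breast histogram.
   At aggressive clip limits the fat/dense intensity valley that the
   multi-threshold segmentation relies on is destroyed (phantom
   dense-fraction MAE degrades from ~0.02 to ~0.17 at clip 0.01), so
   gentleness here is a correctness choice, not a cosmetic one.
5. **Background subtraction.**  A white top-hat: the image minus its
   morphological opening with a disk of radius 50 px (at ~100 µm native
   pixel spacing; scale the radius with pixel size at other resolutions).
   This suppresses broad background and keeps thin bright detail.  The
   decomposed (octagonal) disk approximation is used for speed.
6. **Multi-thresholding.**  Seven cut-offs of the equalised breast
   pixels: Otsu, isodata, mean, median, triangle, maximum entropy
   (Kapur) and minimum cross entropy (Li).  A degenerate single-valued
   histogram yields seven equal cut-offs and a warning.
7. **Twelve regions.**  From the sorted cut-offs c1 ≤ … ≤ c7: six nested
   upper-threshold layers (≥ c1 … ≥ c6), four mid-histogram bands
   [c2,c3) … [c5,c6), the whole breast, and the high-signal core of the
   background-subtracted image (its own Otsu cut).  Regions overlap by
   design.
8. **Dense mask and the area statistic.**  The default dense mask
   thresholds the equalised image at the *median* of the seven cut-offs —
   robust to any single method misfiring; a fixed layer can be configured
   instead.  The area measure is `sqrt(100·|dense|/|breast|)`, in
   [0, 10], exactly 10 when the whole breast is dense and 0 when none is.

   The dense rule operates on the CLAHE image rather than the
   background-subtracted one: subtracting a 50 px opening erases the
   interior of any dense region wider than the disk, which ruins area
   recovery; the background-subtracted image instead contributes the
   "core" region and the feature set.

## Feature vector

A catalogue of 55 measurements: 21 first-order histogram statistics
(moments, quantiles, entropy/energy at 64 bins, robust spreads), 6 GLCM
texture descriptors at distance 1 (64 gray levels quantised over the
whole-breast range, offsets (0,1) and (1,0) symmetrised and averaged), 4
gradient statistics on the region-masked Sobel magnitude, 8 region
morphology numbers and a box-count fractal slope; plus 5 distance-2 GLCM
descriptors and 11 whole-breast shape/global measurements.

The region map — 39 measurements × 12 regions + 5 × 2 + 11 × 1 = 489 —
is configuration with an asserted total, since any split of the catalogue
across regions must preserve the 489-length model contract.  Empty
regions are imputed with whole-breast values and logged, so the vector is
always finite.  GLCM pairs crossing the region boundary are excluded, and
gradients are computed on the region-masked image, so every feature is
invariant to pixels outside its region.

## Volumetric surrogate

A 500-tree random forest regresses the 489 + 15 predictors on the natural
log of the volumetric reference.  The tunable is the variables tried per
split, selected by out-of-bag R² over {p/10, p/3, √p, p/2} (ties to the
smaller).  Prediction refuses feature tables whose column names differ
from the training manifest.  Forest averaging keeps predictions inside
the training outcome range; fixed seeds give bit-identical models.

## Synthetic generators

**Phantoms** place a half-elliptical breast against the left edge, a
triangular pectoral wedge filling the upper-left corner, and a dense
component selected as the top-k pixels of a Gaussian-smoothed noise field
inside the breast interior — so the dense-area fraction equals the
request to the nearest pixel.  Tissue intensities (air 0.01, fat 0.38,
dense 0.68, pectoral 0.74 on a unit scale, Gaussian noise SD 0.035) pass
through a strictly monotone sigmoid "vendor curve" and mild unsharp
masking before 12-bit quantisation; headers are drawn from the
acquisition-parameter means/SDs of the cohort summary.  The phantoms do
*not* emulate scatter, compression-dependent thickness gradients, skin
folds, or vendor-specific curve shapes, so passing recovery tests shows
the chain is correct and well-calibrated on idealised anatomy, not that
clinical accuracy equals the phantom numbers.

**Cohorts** draw genotype Binomial(2, MAF 0.15 — an assumption, not a
measured frequency), age ~ N(53.5, 9.45), BMI ~ N(25.9, 4.46) and
categorical covariates at the published control-group frequencies
(including their missingness).  Three density outcomes share a latent
density factor plus independent noise; the factor shares are calibrated
so the marginal correlations are 0.84 (log-volumetric vs sqrt-area) and
0.91 (log-volumetric vs its image-based prediction).  Default per-allele
effects are −0.138, −0.254 and −0.113 on the three analysis scales.
Case status follows a logistic model on the log-volumetric measure with
log-OR 0.978 per unit; regressions of status on a *surrogate* measure are
then attenuated by the corresponding regression slope (≈ 0.47 for the
sqrt-area scale), which reproduces the published pattern of case-control
estimates without planting them directly.  Case-control sets with fixed
margins are sampled from the prospective model, under which logistic
slopes remain consistent.

**Feature/outcome tables** for the volumetric surrogate use a latent
factor driving both the outcome (noise SD 0.3) and 10 informative
features (loadings 0.5–0.9) among 504 columns — the structure that makes
image features predictive of volumetric density.

## Statistical layer

Density measures are analysed on the square-root (area) and natural-log
(volumetric) scales.  Genotype always enters as a continuous 0/1/2 count.
All Wald intervals are estimate ± 1.96·SE with two-sided normal-reference
p-values, with no small-sample correction.  Complete-case exclusion of
"missing" covariate categories is the default, with a switch to keep them
as factor levels; every fit reports `n_used`.  Collinear designs and
separation in the exposure of interest are errors; quasi-separation in
nuisance dummies (common with 47 cases) triggers a warning and a BFGS
refit rather than failure.

Box-Cox lambda is selected by maximum likelihood over [−2, 2] in steps of
0.05, with non-positive inputs shifted by (1 − min).  The permutation
global test uses the count of per-feature p < 0.05 (simple regressions of
density/age/BMI-adjusted feature residuals on genotype) and the add-one
estimator (1 + #{permuted ≥ observed})/(n_perm + 1); permuted statistics
are vectorised across features, so 10,000 permutations of ~500 features
take seconds.

## Problem sizes and calibration checks

The test suite and the acceptance script use: a 50-phantom suite on a
dense-fraction grid 0.05–0.8 (320×256 px phantoms); volumetric surrogate
runs with 400 training / 1000 test rows; genetic-model calibration with
400 null and 200 alternative replicates at n = 1011; permutation-test
calibration with 100 null runs (199 permutations) and 50 powered runs
(299 permutations, 20 of 100 features at 0.2 SD per allele).  Observed
behaviour at these sizes: dense-fraction MAE ≈ 0.02, truth/estimate
correlation ≈ 0.999, breast Dice ≈ 0.98, surrogate held-out r ≈ 0.89,
type-I error within binomial noise of 5%, planted-effect recovery to
±0.01, permutation power ≈ 1.0.

## Known limitations

* The exact thresholding catalogue, region definitions and 55-measurement
  list are configurable stand-ins behind a fixed structural contract
  (7 cut-offs, 12 regions, 489 features); other catalogues can be dropped
  in without touching the model code.
* CASAM-Area is intensity dependent and therefore vendor dependent; no
  cross-vendor harmonisation is attempted, and the volumetric surrogate
  should be retrained per machine type.
* The pectoral detector assumes a roughly straight muscle edge in the
  upper-left; curved or faint muscle boundaries are out of scope of the
  phantom evidence.
* No raw-image decoding, no physics-based volumetric reconstruction, no
  genome-wide analysis (a single additively coded SNP only), and no
  multiple-testing correction beyond the permutation global test.
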