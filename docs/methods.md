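# Methods

`photobf` estimates percent body fat (%BF) from two calibrated
photographs of a standing person — a back profile and a side profile —
taken against a chroma-key green background. The method has four parts:
silhouette geometry, body-volume reconstruction, trunk-shape encoding,
and a supervised regression against a dual-energy x-ray absorptiometry
(DXA) criterion, evaluated with dependent-correlation and agreement
statistics.

## Capture assumptions

The pipeline assumes the capture protocol it was designed for: a uniform
green backdrop, the subject in close-fitting clothing, the back-profile
pose with arms and legs visibly separated, the side-profile pose with
arms close to the body and legs together, and a measured standing height
for calibration. A standardized camera distance (treated as recorded
metadata, not enforced) keeps perspective distortion comparable across
subjects. Violations surface as typed errors: `EmptyMaskError` (nothing
but background), `FramingError` (subject cut off by the frame),
`PoseError` (limbs not separable).

## Silhouette geometry

**Chroma keying.** Background pixels are classified in HSV space: hue
within `hue_tol` (default 0.10 on skimage's [0,1) hue circle) of pure
green (1/3) and saturation at least `sat_min` (0.25). HSV tolerates
uniform brightness changes of the backdrop, which raw RGB thresholds do
not. The largest 4-connected foreground component is kept and enclosed
background holes smaller than 0.5% of the foreground area (clothing
speckle) are filled; larger holes are preserved as evidence of a capture
problem. All three thresholds are configuration, not canon — real
wardrobe/skin/backdrop combinations may need different windows.

**Symmetrization.** Each mask is rotated about its foreground centroid
to the angle in ±15° that minimizes the XOR count between the mask and
its mirror about the centroid column, coarse 1° sweep refined to 0.1°.
This removes small camera/stance tilts before any vertical measurement.

**Height calibration.** `scale_cm_per_px = measured height / foreground
pixel height`. The raster is never resampled; all conversions to cm go
through this scale factor.

**Key points and segmentation.** On the back profile, the crotch is the
topmost background point of the between-legs gap; the armpits are the
deepest convexity defects of the contour (contour from marching squares,
hull from scipy) on each side of the midline, gated to lie laterally at
least a quarter of the body half-span from the centroid so neck or
waist concavities cannot win; the head top is the topmost foreground
pixel. Straight separation lines through these points partition the
silhouette into head, trunk, two arms, and two legs: arms outside the
vertical armpit lines below armpit level, legs below the crotch split at
the crotch column, head above the minimum-width row (the neck) in the
upper quarter of body height (the top 5% is excluded so the crown of the
head cannot masquerade as the neck), trunk the remainder. The partition
is exact by construction: every foreground pixel lands in exactly one
component. Straight lines are an approximation — a contour-following
split would assign a slightly different shoulder/hip boundary — and the
phantom ground-truth labels follow the same convention.

## Body volume (BV_PHOTO)

The body is modelled as a stack of elliptical slices, one per pixel row
along each component's main axis (principal axis of its pixel set; limbs
are rotated upright before slicing so an angled arm is measured across,
not horizontally). The slice's long axis is the component's back-profile
width at that row (interrupted rows sum their run lengths); the short
axis is the side-profile width at the same height below the head top.
Head and trunk take the side width directly; limbs are circular
(short = long) because the side profile does not resolve individual
limbs. Slice area is the analytic π/4 · w_back · w_side; a rasterized
pixel-counting mode exists for fidelity checks and converges to the
analytic value with resolution. Volume is Σ area × slice thickness
(thickness = the calibration scale), reported in liters. A >2%
disagreement between back and side silhouette heights raises
`HeightMismatchError`.

On closed-form solids the reconstruction is within 2% at 0.25 cm/px and
errors shrink with resolution; on full humanoid phantoms the median
error against the closed-form primitive sum is under 1% at 0.5 cm/px.

## Trunk shape (BS_PHOTO)

Twelve rows, linspace-inclusive between the left armpit row and the
crotch row, are sampled on both profiles. The front curve FC is the
trunk width (cm) of the back profile at each row; the side curve SC is
the signed distance (cm) from the side silhouette's back edge to the
central bodyline — the vertical through the top of the head — positive
toward the back (the sign and the back-edge choice are conventions; a
`facing` flag states which way the subject faces). FC and SC are
clustered **separately** with K-means (10 restarts, seeded) for each
k = 2..10 in raw cm, and k is chosen by the Calinski–Harabasz criterion
(B/(k−1))/(W/(n−k)). Each subject's shape feature is the pair of one-hot
vectors of its nearest-centroid clusters, ties to the lowest index. No
standardization is applied before clustering: both curves are already in
the same units, and scale (overall girth) is legitimately part of shape
here.

## Prediction models

Three nu-SVR models (RBF kernel) are compared:

| model          | features                                   |
|----------------|--------------------------------------------|
| `nophoto`      | age, sex, race, BMI                        |
| `volume`       | + BV_PHOTO (L)                             |
| `volume_shape` | + FC one-hot + SC one-hot                  |

Continuous features (age, BMI, BV) are standardized with training-fold
moments; indicators pass through. RBF kernels on raw mixed-unit features
(years vs kg/m² vs liters) would let one unit dominate the metric.

Hyperparameters are found by exhaustive search: gamma and cost over
2^x, x = −10..10 (21 values each), nu over 0.1..1.0 step 0.1 — 4410
combinations — each scored by internal 3-fold CV mean squared error on
the training set, ties to the smaller exponents. Selecting on
resubstitution error instead (available via `selection="resubstitution"`)
degenerately favors memorizing RBF settings; internal CV is the default
for that reason. For end-to-end runs a documented coarse grid (exponents
{−10,−6,−2,2,6,10}; nu {0.2,…,1.0 step 0.2}; 180 combinations) is used
via `SVRConfig.coarse()`; the full grid remains the `SVRConfig()`
default. nu = 1.0 is included as printed; the libsvm backend accepts it.

**Evaluation protocol.** One round of 3-fold cross-validation per
cohort: subjects are shuffled (seeded) into three near-equal folds; in
each fold the shape clusters are fit on the two training folds only, the
test fold is encoded by nearest centroid, all three models are
grid-search-trained, and the held-out fold predicted — every subject is
predicted exactly once. Children (6–18 y) and adults (≥19 y) are
modelled as separate cohorts. Each fold records a provenance trail
(training ids, scaler moments, centroid hash, chosen hyperparameters)
from which the no-leakage property is asserted mechanically in the test
suite. A `rounds` option repeats the whole protocol with fresh shuffles;
the default is one complete round.

Predictions outside (0, 70) %BF are reported unclipped with a warning:
silent clipping would hide a badly specified model.

## Agreement statistics

* **Meng–Rosenthal–Rubin Z** for two dependent correlations sharing the
  criterion: Z = (z₁ − z₂) √((n−3)/(2(1−r₁₂)h)), with
  h = (1 − f·r̄²)/(1 − r̄²), f = min(1, (1−r₁₂)/(2(1−r̄²))),
  r̄² = (r₁² + r₂²)/2, zᵢ the Fisher transforms. Equal correlations give
  Z = 0 by definition; a correlation of exactly ±1 is rejected rather
  than silently producing an infinite transform.
* **Lin's concordance coefficient** with population (1/n) moments, per
  Lin's original definition: 2·cov/(var_x + var_y + (mean gap)²).
* **Bland–Altman** absolute (y−x) and relative (difference over pairwise
  mean) analyses with limits of agreement mean ± 1.96 × sample SD (n−1).
  The limits are limits of agreement, not confidence intervals for the
  mean difference, and are labelled accordingly.

## The synthetic-data generator

No photograph cohort ships with the package, so validation runs on
synthetic data generated by `photobf.synthetic`:

**Phantoms** are stylized humanoids assembled from primitives with
closed-form volumes: a spherical head, circular neck, elliptic trunk
with piecewise-linear taper (breakpoint mid-trunk), circular-section
arms tilted 25° outward, and cylindrical legs. Every pipeline branch is
exercised: the arm wedges create armpit concavities, the leg gap a
crotch, the neck a minimum-width row, the tapers FC/SC variation. The
arm apex is embedded 1 cm into the trunk so rasterization cannot
disconnect it; the resulting junction slivers are neglected in the
closed-form sum and stay far below the 3% phantom tolerance. Landmarks
are emitted analytically from the construction geometry.

**Cohorts** sample anthropometry matching a mixed community sample
(adults: age 38 ± 12 y, height 169 ± 8 cm, BMI 28.7 ± 6.6; children:
age 11 ± 3 y, height 148 ± 15 cm, BMI 20.4 ± 4.4; ~47% female, 47–61%
African American; all truncated at ±3 SD). Each subject is physically
realized as a phantom whose trunk/limb widths are solved (in closed
form — widths enter volume quadratically) so body volume matches
weight at an assumed mean tissue density of 1.04 kg/L; infeasible width
multipliers are capped to [0.55, 1.9] and flagged. Trunk taper follows
one of three archetypes — uniform, android (belly-forward), gynoid
(hip-heavy) — planting a fat-distribution signal that BMI and volume do
not carry. The criterion is then generated as

    %BF = −10 + 0.1·(BV/height_m) + 1.0·BMI + 8.0·female + 3.0·shape_class + N(0, 3)

truncated to (5, 60). The coefficients were chosen once to reproduce the
adult marginals above (mean %BF ≈ 32, SD ≈ 9) with a realistic 3 %BF
criterion-model residual, a strong BMI backbone, a sex offset, and a
moderate shape effect. Default cohort size is n = 200, the scale a
practitioner would pilot at and large enough (by simulation) for the
shape effect to be detectable at α = 0.05 in a 3-fold CV.

**What the generator does not emulate** — and therefore what passing
tests cannot show about real photographs: lighting gradients and
shadows, clothing folds and hair, skin/background chroma overlap,
perspective foreshortening, postural asymmetry beyond a rigid tilt,
arms contributing to the side silhouette, and any real covariance
between fat distribution and demographics. Results on phantoms bound
the geometry and protocol logic, not photographic robustness.

## Numerical choices and degeneracies

* Rotation/resampling uses nearest-neighbour (order 0) so masks stay
  binary; symmetrize search resolution 0.1°.
* Curve rows and side-row matching use rounded nearest-row lookup at the
  same height below the head top (absolute height, not per-component arc
  length).
* K-means ties and nearest-centroid ties resolve to the lowest index;
  grid-search ties to the first (smallest-exponent) combination.
* Degenerate inputs raise typed errors rather than returning sentinel
  values: empty masks, unseparated limbs, empty components, zero volume,
  zero-variance targets, <11 subjects for clustering, <30 for CV.
* All stochastic stages (K-means restarts, fold shuffles, generators)
  take explicit seeds and are bit-reproducible given them.

## Problem sizes

The shipped validation uses sizes chosen to keep a full run on one CPU
comfortable: 50 random phantoms for landmark/volume recovery, 20 trials
per planted k ∈ {2,3,4} for cluster selection, 10⁴ pairs for
Bland–Altman coverage, and one n = 200 cohort at 0.5 cm/px with the
coarse grid for the end-to-end protocol. The full 21×21×10 grid and
finer rasters are available through configuration.

## Known limitations

* The straight separation lines and circular limb sections are
  approximations; both are documented conventions, not fitted choices.
* Arms are excluded from the side profile model; on real side
  photographs arms held close to the body thicken the trunk silhouette
  and would inflate trunk slices.
* Lin's CCC is reported without a confidence interval; Bland–Altman
  assumes a single measurement pair per subject.
* The printed grid includes extreme RBF settings (gamma = 2¹⁰) that are
  never selected in practice but dominate grid-search runtime; the
  coarse grid trades exhaustiveness for speed and is always labelled in
  provenance.
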