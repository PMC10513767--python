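# Methods

This note documents the models, surrogates, and numerical choices behind
the package: what each component computes, which constants matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## 1. Classifier adapter and fixture CNN

All saliency methods consume a classifier through a three-method contract:
`class_scores(image)` (logits), `activations(image, layer)` (the feature
maps Aᵏ of a named convolutional layer, shape (h, w, K)), and
`score_gradients(image, layer, class_index)` (∂y_c/∂Aᵏ, same shape). Any
network wrapped in this contract can be explained; the study-scale
EfficientNet-class model is deliberately out of scope here.

The shipped `FixtureModel` is a small numpy CNN: same-padded 3×3
convolutions with optional stride, an elementwise nonlinearity (`relu`,
`softplus`, or `linear`), global average pooling, and a linear head.
Backpropagation is written by hand (the adjoint of a same-padded
correlation is a same-padded convolution; stride adjoints scatter into the
strided grid). Two consequences matter for testing:

* gradients are verified against central finite differences (step 1e-3,
  relative tolerance 1e-4). With ReLU this oracle is only valid away from
  kinks — a pre-activation within the step of zero makes the two-sided
  difference straddle the kink — so the gradient-check matrix uses smooth
  activations plus ReLU configurations with a verified kink margin;
* the "layer" whose activations a CAM consumes is the *post-nonlinearity*
  map, so gradients at the top layer are spatially uniform (head weight /
  hw) and only become spatially structured at lower layers. Oracle tests
  therefore exercise the lower layer.

Weights serialize to JSON (nested lists) so fixtures are
ecosystem-independent. Images are float [0,1], channel-last, origin
top-left. The "final convolutional layer" defaults to the last entry of
`layer_names` and is overridable per call.

## 2. Saliency methods

All five methods return a map at input resolution in [0,1]: the raw map is
bilinearly upsampled and min-max normalized; an exactly constant raw map
normalizes to all zeros rather than 0/0.

* **Grad-CAM**: αₖ = mean over space of ∂y_c/∂Aᵏ; L = ReLU(Σ αₖAᵏ).
* **Grad-CAM++**: the standard closed form built from second- and
  third-order powers of the first gradient, restricted to positive partial
  derivatives: per-location weights a = g²/(2g² + Σ A g³) (0 where the
  denominator vanishes), channel weight w = Σ a·ReLU(g). The method's
  defining description ("a weighted combination of the positive partial
  derivatives") requires this form.
* **Eigen-CAM**: reshape the stack to (hw × K), take the first right
  singular vector V₁, map = A·V₁, sign fixed so the map sums ≥ 0. No ReLU,
  no class dependence.
* **Score-CAM**: each channel map is upsampled and per-channel min-max
  normalized into a mask Hᵏ (constant channels give Hᵏ ≡ 0, avoiding 0/0);
  αₖ = f_c(X ⊙ Hᵏ) − f_c(X_b) with the all-zero image as default baseline;
  exactly K+1 forward passes beyond activation extraction.
* **LIME**: SLIC superpixels as perturbation units; binary designs drawn
  Bernoulli(1/2) with the all-ones row forced first; switched-off segments
  painted with the mean lesion-surround color; sample weights
  π(z) = exp(−D²/σ²) with D the cosine distance between binary vectors
  (σ = 0.25); weighted ridge fit (penalty 1e-3, free intercept). The
  surrogate weights render to a signed map via w ↦ 0.5 + w/(2·max|w|), so
  0.5 means no influence and warm/cold encode positive/negative influence.
  Sample count, σ, and segmentation granularity are explicit knobs
  (defaults 1000 / 0.25 / 24) — no published values exist for them.

Explanations default to the melanoma class (index 1 of the fixture): the
evaluation design only grades maps of melanoma-positive predictions.

## 3. Synthetic lesions

The generator stands in for the study's dermoscopy images. A lesion is a
star-convex outline

    r(θ) = r₀ · e(θ) · (1 + b(θ)) · (1 + δ(θ))

with r₀ = 0.22·min(canvas) (canvas default 128×128), e a global elliptical
elongation (amplitude 0.28) that pins the mask's principal axes to the
generator frame, b a per-quadrant bump signature, and δ a high-harmonic
wiggle (relative amplitude 0.13, 14 cycles/revolution) windowed to exactly
the prescribed fraction of the arc.

**Why bumps, not quadrant scales.** A harmonic-1 radial scaling is, to
first order, a *translated* circle, and harmonic-2 an ellipse; both are
absorbed by the measured centroid and principal axes, so per-quadrant size
offsets produce lesions that grade symmetric. Quadrant dissimilarity must
therefore live in localized profile shape: a mid-quadrant outward lobe
(amplitude 0.42), a flat arc, an inward notch (0.38), or a lobe with a
multiplicative lightness shift (0.30, ≈12 ΔE). Bumps occupy the central
70% of the quadrant arc so the modest swing of the measured quadrant
boundaries cannot clip them, and are mirror-symmetric about mid-quadrant
so canonical mirroring is well defined. Level 0 uses four identical lobes,
level 1 three lobes plus a flat arc, level 2 lobe / flat / shaded notch /
shaded lobe — every pair distinct in shape or color.

**Border.** The wiggle's arc fraction carries the B level (level midpoints
0 / 0.25 / 0.75); its harmonic (14) sits well above the smooth-outline fit
order (9) used by the grader, while the bump spectrum sits below it, so
the two signals separate cleanly.

**Color.** Pigment comes from a fixed palette (brown base; black, red,
blue-gray blobs, one per color beyond the first; blob radius 0.30·r₀).
Blob centers are sampled from a strongly eroded mask so pigment never
reaches the border band (border truth is geometric), or concentrically at
the centroid in `central_blobs` mode (used by map fixtures so the
abnormality region spreads over all four quadrants). The ground-truth
color-abnormality map is the union of non-base blobs. Gaussian texture
noise (σ = 0.02) keeps clustering non-trivial; the background is a light
skin tone with a mild vignette.

**Border NA.** An off-canvas lesion is rendered oversized (3.2·r₀) and
centered on the image edge, so the visible piece touches three frame sides
and well over half its outline is unevaluable. Shape modifiers are
suppressed for these lesions — an off-canvas border cannot express a
border level, which is exactly what NA encodes. Recovery statistics are
computed on evaluable (on-canvas) lesions; the NA path is tested
separately.

**What the generator does not emulate**: dermoscopy artifacts (hairs,
rulers, gel), photorealistic pigment textures, the 18/82 class balance of
a real archive, or inter-grader disagreement. Passing tests show that the
pipeline's rubric surrogates are internally consistent and recover
constructed ground truth — not that they reproduce human grading of real
lesions.

## 4. Clinical grading surrogates

Rubric constants were calibrated once on the generator's level-0/level-2
extremes and frozen; all are module-level and overridable per call.

* **Quadrants**: the lesion is split at its centroid along the mask's
  principal axes (rotation invariance; orientation is not part of the
  rubric). Pixels are assigned by angle, so each boundary half-axis
  belongs to exactly one quadrant; a nearly isotropic mask (eigenvalue
  ratio < 1.02) falls back to image axes, where arbitrary eigenvectors
  would cut through pixel centers unevenly.
* **Asymmetry**: each quadrant is canonicalized to a (|u|, |v|) occupancy
  grid (~2 px cells; finer grids alias and depress the overlap of
  identical shapes). Two quadrants are similar when mirrored IoU ≥ 0.75
  (either orientation — rotationally congruent quadrants canonicalize to
  transposes) *and* the Lab distance of their median colors is ≤ 10 ΔE.
  The median, not the mean, so a localized pigment blob in one quadrant
  does not register as whole-quadrant color dissimilarity. The grade
  counts the largest mutually-similar clique: 4 → 0, 2–3 → 1, ≤1 → 2.
* **Border**: the longest contour is resampled to a 360-point radial
  profile about the centroid and fit with harmonics ≤ 9; the profile is
  split into 36 arc segments, and a segment is irregular when its RMS
  radial residual exceeds 0.045 of the mean radius or the Lab spread of
  pixels just inside it exceeds 25. The residual-against-smooth-outline
  statistic was chosen over raw curvature variance because it is robust to
  discretization noise on smooth contours and monotone in the generator's
  perturbed-arc fraction; the color clause threshold sits above
  pigment-graze noise since the generator never constructs color-abnormal
  borders. Irregular fraction f: 0 → 0, (0, 0.5] → 1, > 0.5 → 2. A
  contour >50% on the image frame grades NA.
* **Color**: lesion pixels are k-means clustered in Lab (k = 5), centroids
  closer than 14 ΔE are merged (count-weighted), merged clusters under 5%
  of the lesion are dropped and their pixels reassigned to the nearest
  kept cluster. With a discrete palette this merge-based count is
  deterministic and exact, which is why it replaced a gap-statistic k
  selection that proved unstable on small lesions. Count → grade
  (1/2/≥3 → 0/1/2); non-dominant clusters form the derived abnormality
  map.

Diameter and evolution are not graded (no scale bar; single time point).

## 5. Map grading

Warm/cold are operationalized on the normalized map value, calibrated to
the blue→red rendering: warm = value ≥ 0.6, cold = value in [0.2, 0.6).
Grading never reads rendered colors, so recoloring cannot change grades.

* **Asymmetry**: quadrant descriptors (mean value, warm fraction) with
  similarity tolerances 0.06 and 0.20; clique counting as in clinical
  grading.
* **Border**: over a morphological ring of width max(3 px, 5% of the
  equivalent radius) around the contour: warm fraction > 0.5 → 2; any warm
  or cold fraction > 0.5 → 1; else 0; clinical NA propagates. A band that
  is majority-cold with zero warm grades 1 under the partial clause — the
  rubric's grade-0 wording couples "no highlight" with "≤50% cold", and
  the partial clause is the consistent reading.
* **Color match**: over the abnormality pixels, warm overlap > 0.75 → 0,
  in [0.25, 0.75] or cold overlap > 0.75 → 1, else 2. The rubric's prose
  for total agreement ("≤ 75% for heat colors") contradicts its own
  partial band and is implemented as > 75%. An empty abnormality map
  grades 0: nothing to mismatch, and the difference statistic stays
  meaningful for one-color lesions. Range endpoints are inclusive exactly
  as written, pinned by tests at one-pixel resolution around the cuts.

Synthetic map fixtures realize prescribed quadrant intensities, band
warm/cold fractions, and abnormality warm overlap by assigning values
stratified per quadrant in deterministic angular order, so the global
fractions hit the prescription (within rounding) without disturbing
quadrant symmetry. Fixture prescriptions keep ≥5% clear of every rubric
boundary; the 50-fixture suite grades with 100% accuracy.

## 6. Agreement aggregation

Pair classification is |c − m| ∈ {0, 1, 2} → total / partial / none, with
NA on either side excluding the pair (the border denominator shrinks, as
in the 190-vs-200 structure of the reference table). Percentages are kept
at full precision and rendered at two decimals (table style) or one
decimal (combined rates). Ranking is by combined rate, ties broken by
total-agreement rate, then name. The algorithmic grader is duplicated
per configured grader count (default 2) so denominators match a
two-reader layout; the aggregation itself is denominator-agnostic.

The published counts are stored as package data and re-aggregated through
the same code path as synthetic records; the one cell whose printed
percentage disagrees with its own count (LIME / border / none: 32/190 =
16.84% vs printed 6.84%) is flagged as an erratum rather than reproduced.

## 7. Problem sizes and reproducibility

Oracle tests run on 12×12 images with 2–3 channel layers, where exhaustive
finite differences and 2⁶ LIME enumerations are exact and fast. The
recovery check uses 200 lesions at 128×128 sweeping all 27 grade cells at
level midpoints; the analysis drivers use a 30-lesion cohort with a 150
sample LIME budget. Every stage is seeded: cohorts, LIME designs, k-means
initializations, and the fixture model all derive from explicit seeds, and
a full pipeline run is reproducible bit-for-bit from (config, seed); CSV
floats are rounded before writing.

## 8. Known limitations

* The asymmetry surrogate measures deviation from 4-fold reflective
  congruence about the principal axes. Shapes whose asymmetry lives
  entirely in harmonics 1–2 of the radial profile are invisible to any
  centroid-referenced method, including this one; the generator encodes
  asymmetry in localized features for that reason.
* At asymmetry level 2 the measured quadrant boundaries occasionally blend
  two signatures enough that one pair passes the similarity test, grading
  1 instead of 2 (a few percent of lesions); recovery stays well above the
  90% requirement.
* The fixture CNN is untrained; synthetic-cohort agreement rates
  characterize the pipeline, not any clinical claim about the techniques.
* Grader duplication models the reference denominators, not inter-reader
  variability; qualitative preference ranking is out of scope.
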