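# Methods

This note records the models, calibration and numerical choices behind
`scintiseg`, and what the synthetic evaluation does and does not
establish about real clinical data.

## Phantom cohort model

Each phantom is one posed hand: a palm ellipse, a metacarpal "knuckle
bar", four finger capsules, a thumb capsule and a wrist block,
rasterized analytically on a square grid (default 256 × 256) and posed
per view (palmar / dorsal / two obliques) by a small rotation and
translation with seeded jitter. The raw `normal` mask is the full
silhouette, so lesion masks always overlap it — reproducing the
non-exclusive annotation style that severity fusion exists to resolve.

Latent intensity is piecewise constant (defaults, in arbitrary count
units: background 1, normal 150, low 400, high 800), blurred by a
Gaussian point-spread function (σ = 1.2 px), Poisson noise is applied
pixel-wise, and counts are linearly mapped (fixed factor
`display_max / count_scale_max = 100 / 1000`) and rounded into the
0–100 display scale. Gamma-camera counts are Poisson-like and the
annotator worked on fixed-scale display images, which this mimics; no
collimator, scatter or depth physics is simulated.

### Calibration

The emulated dataset is a *fixed* cohort whose composition statistics
are known, not a draw from a superpopulation. The generator therefore
fixes composition where the targets are counts and randomizes
everything else:

* **Patient states.** Each patient is healthy, low-only, high-only or
  both-classes. The four proportions (0.2274 / 0.2164 / 0.0440 /
  0.5123) were solved from the five dataset statistics (two pixel
  fractions, three empty-image counts) together with the per-image
  lesion rates; for 48 patients they are allocated by largest remainder
  (11 / 10 / 2 / 25) and shuffled. The strong low–high comorbidity
  (both ≫ high-only) is required by the joint count of 45/192
  lesion-free images; the dataset publishes no patient-level joint
  distribution, so the split between the remaining states is a design
  choice.
* **Lesions per image.** For an affected patient, each view draws a
  zero-inflated Poisson number of lesions per class — low:
  (λ = 3.5799, π₀ = 0.0007); high: (λ = 4.0809, π₀ = 0.0111) — the
  unique pair matching both the expected empty-image counts and the
  per-class pixel masses given the integer patient composition. The
  only remaining expectation bias is the neither-count (45.44 vs 45,
  well under one per-seed standard deviation).
* **Lesion sizes.** Pixel counts are lognormal with the published
  mean ± sd per class (low 62.81 ± 82.55 px, high 121.25 ± 130.65 px),
  rounded and clamped to [1, 3000]. A lesion is rasterized as the
  first-n-pixels-by-distance prefix of a disk, so every component holds
  *exactly* its sampled count, and a one-pixel separation constraint
  (full 3 × 3 dilation) prevents 8-connected components from merging;
  mean component size is therefore unbiased up to placement skips.
* **Placement.** Candidate centers are 20 joint-like loci (three per
  digit, palm, wrist) with ± 5 px jitter; a lesion is accepted only if
  the silhouette's Euclidean distance transform at its center exceeds
  its outer radius. Lesions are placed largest-first to keep
  size-dependent skips rare (≲ 0.1 % of lesions at default scale);
  failures after 60 attempts are skipped with a logged warning.

8-connectivity defines a lesion component throughout — the standard
choice for blob-like 2D lesions.

### What the phantom does not emulate

Real scans have anatomical variability, acquisition artifacts,
diffuse/irregular lesion shapes, and — critically — human annotation
noise at lesion boundaries (the dominant error source for low
inflammation in the clinical study). Phantom lesions are compact,
high-contrast disks with exact labels, so segmentation scores on the
phantom are *optimistically* high and are not comparable to the
clinical-table values; passing tests establish the correctness of the
evaluation machinery and the calibration of the cohort statistics, not
clinical performance.

## Threshold segmenter numerics

* **Kernel rule.** `k = round(max(3σ, 1))`, +1 if even, with
  round-half-away-from-zero. The argument is ≥ 1 so the sign is
  irrelevant, and 3σ lands on .5 only off the default σ grid.
* **Border handling.** Reflect (half-sample symmetric) padding; it
  avoids darkening hand edges, where lesions can sit.
* **Bands are inclusive** (`lower ≤ v ≤ upper`): on an integer
  threshold grid this keeps the search exhaustive.
* **Parameter count.** σ is per class (nine parameters, not seven);
  the three classes are fully independent detectors.
* **Fit objective.** Mean modified Dice over *training* images per
  class; the validation bucket is used only for inner-fold model
  selection. Threshold levels default to the integers 0 … max(train).
* **Tie-breaks.** Among equal-scoring candidates: smallest σ, then
  smallest lower, then smallest upper (and the lowest inner-fold index
  during selection), making fits bit-reproducible.
* **Complexity.** For each (image, σ) the image is smoothed once; the
  full (lower, upper) Dice table then comes from sorted pixel values
  via cumulative counts, so all O(L²) threshold pairs cost two
  `searchsorted` calls per image, and nested cross-validation shares
  the per-image tables across its nine overlapping inner fits.

## Evaluation conventions

* Per-class Dice/IoU compare the model's **raw independent masks**
  (a pixel may carry several classes) against the class's binary slice
  of the severity-fused reference; confusion matrices use fused
  exclusive maps on both sides. Which masks feed the per-class score
  only matters on multi-class pixels; this choice is surfaced here
  because the convention is not otherwise fixed.
* The combined inflamed class is the clipped sum of the low and high
  prediction masks; references combine via fused labels (exclusive, so
  plain addition).
* The "all" column is the unweighted mean of the three per-class
  scores; fold aggregation is mean ± **sample** standard deviation
  (ddof = 1), the convention that best reproduces the published
  thresholding-table ± values — the published source does not state
  which formula was used.
* ROC decision rule: call an image inflamed when its predicted
  inflamed-pixel count ≥ t, sweeping t = 0 … N+1 (N = pixels per
  image). Extending to N+1 guarantees the (0, 0) endpoint even for an
  all-inflamed prediction. AUC by the trapezoid rule; the 1-pixel
  operating point gives sensitivity/specificity.
* Patient-leakage assertion is part of the harness itself, not only of
  the tests.

## Problem sizes

The calibration checks generate five independent default cohorts
(5 × 192 images, ≈ 25 s total) and test each statistic within three
standard errors across seeds; the nested-cross-validation and pipeline
tests run on reduced cohorts (6–12 patients, 48–64 px images, small
σ/threshold grids), chosen so the whole suite completes in well under a
minute while still exercising every code path at full fidelity. The
full 48-patient pipeline with the default 40-σ × integer-threshold grid
is supported and takes on the order of tens of minutes on one core.

## Known limitations

* The phantom's intensity model is piecewise constant; real tracer
  uptake is graded, so learned thresholds on phantoms are sharper than
  clinically plausible ones.
* Lesion counts per image and per-patient joint state distributions are
  not published for the real dataset; those parts of the calibration
  are modeling choices, constrained only by the published summary
  statistics.
* The external-prediction path evaluates mask files but provides no
  training of CNN segmenters.
* Only hand/wrist views are modeled; feet and whole-body acquisitions
  are out of scope.
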