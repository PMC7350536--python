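# Methods

`contourqa` implements an automated quality-assurance (QA) workflow for
organ-at-risk (OAR) contours on thoracic CT, built around a segmentation
model that is fine-tuned by active learning on noisy clinical annotations.
This note documents the models, the conventions fixed where the problem
statement leaves freedom, the synthetic phantom used for all testing, and
the known limitations.

## The workflow

Five steps, orchestrated by `pipeline.run_all`:

1. **Data split.** Cases are divided into a *gold* set (expert-verified
   contours), a *candidate* set (the first-enrolled block, annotations of
   mixed quality), and randomly assigned *validation* and *test* sets
   (`pipeline.split_assign`, seeded, without replacement). The four sets are
   disjoint by case and the test set never touches training, selection, or
   criteria fitting.
2. **Initial training** of a segmentation backend on the gold set.
3. **Active-learning fine-tuning** on the candidate pool (below).
4. **Criteria fitting.** The fine-tuned model is applied to the validation
   set, whose contours are assumed error-free; per-organ slice-wise DSC/HD
   statistics define the pass criteria.
5. **Detection.** Model plus criteria are applied to the test set; each
   (slice, organ) sample is flagged pass/fail and the flags are scored
   against ground-truth error labels.

## Contour metrics (`metrics`)

All comparisons are per (slice, organ) between binary masks on the CT pixel
grid.

* **DSC** = 2|A∩B| / (|A|+|B|).
* **HD** is the classical symmetric 100th-percentile Hausdorff distance
  between boundary-pixel centers, Euclidean in isotropic pixel-index units
  (no spacing scaling) — thresholds are quoted in pixels. HD95 was the
  rejected alternative; the classical definition is the one the reported
  per-organ threshold magnitudes are consistent with. A boundary pixel is a
  true pixel with at least one false 4-neighbor or a grid edge.
* **Empty-set conventions** (not part of the source formulas; fixed here so
  missing contours always fail): both masks empty → DSC 1, HD 0 ("trivially
  correct"); exactly one empty → DSC 0, HD ∞. An infinite HD can never
  satisfy a pass criterion.
* Validation summaries use the sample (n−1) standard deviation and exclude
  slices without manual contours and non-finite HD values.

## Rasterization (`io_rtstruct`)

Masks are (row, col)-indexed, 0-based; patient-to-pixel mapping uses
`ImagePositionPatient`/`PixelSpacing` with identity orientation. A pixel is
inside a contour iff its *center* is inside the polygon set under the
even-odd parity rule, implemented as a half-open scanline crossing test
(an edge counts when it spans the pixel's y strictly, and the crossing lies
strictly right of the center). This makes nested contours produce holes,
multi-polygon slices combine by parity, and a 10×10 mm square aligned with
pixel boundaries cover exactly 100 pixels on a 1 mm grid. Contours attach to
the nearest slice within half a slice thickness. ROI names map to the five
canonical organ labels through an editable alias table (longest-substring
match), because multicenter naming drift is part of the problem the tool
exists for.

## Uncertainty and candidate selection (`uncertainty`, `active_learning`)

Image uncertainty is the mean per-pixel confidence shortfall
U = (1/m) Σ (1 − max(pᵢ, 1−pᵢ)) over all m pixels of the image — 0 for a
binarized map, 0.5 at the decision boundary, invariant under p → 1−p. With
multiple organ channels, a slice's selection-level U is the mean of the
per-channel values; the binary formula is kept intact per channel.

Representativeness combines informativeness and annotation quality:
R = U · DSC / HD, where DSC and HD compare the model's prediction with the
candidate's manual annotation. Conventions:

* slices with no contours at all (manual or predicted) take DSC = HD = 1 and
  are ranked purely by U;
* HD is floored at ε = 1 px in the ratio (a perfect contour has HD 0);
* image-level DSC is the mean over organs where either mask is non-empty;
  image-level HD is the mean over the same organs with per-organ ∞ capped at
  the image diagonal, so one missing organ degrades but does not zero R.

Each selection round stratifies the remaining pool into slices with and
without manual contours, sorts each stratum by R (ties: higher U, then
stable id), and takes the top ⌊fraction·stratum⌋ from each. The fraction
applies to the *remaining* pool, so two rounds at 30% consume
0.3 + 0.7·0.3 = 51% of the candidates. Selected contour-free slices enter
training as explicit all-background negatives. Fine-tuning continues from
the previous round's weights (configurable; restarting from the gold model
is the rejected default).

## Pass criteria and detection scoring (`qa`)

Per organ, from validation statistics: DSC_test > mean_DSC − k·σ_DSC or
HD_test < mean_HD + k·σ_HD, with k = 1.96 and strict inequalities. The
either-criterion rule exists because small structures legitimately score low
DSC with tight HD. Thresholds are reported at display precision (DSC 2
decimals, HD 1 decimal) with full precision retained internally.

One published reference table (`reference.py`) is shipped as input data for
the threshold arithmetic. Its spinal-cord DSC criterion (0.75) does not
follow from the formula (0.86 − 1.96·0.06 = 0.7424 → 0.74) while all nine
other entries do; the package always applies the formula and never
hard-codes the 0.75.

The pass/fail decision is binary, but an ROC needs a continuous score, whose
construction is this package's own: the *conformity score*
max((DSC − thr_DSC)/σ_DSC, (thr_HD − HD)/σ_HD) — the signed margin to the
nearer-passed criterion in SD units, positive iff the sample passes, and
monotone in both metrics. AUC sweeps a threshold over it (trapezoidal, via
scikit-learn; the hard decision is threshold 0). Detection reports count a
"fail" verdict as a positive (error) prediction: BA = (SEN + SPE)/2,
SEN = TP/(TP+FN), SPE = TN/(TN+FP), per organ and pooled. Samples that are
empty in both manual and predicted masks count as error-free and are
excluded from criteria fitting (only slices with manual contours inform the
statistics).

## Segmentation backends (`segmentation`)

The QA method is architecture-agnostic, so the package ships a three-method
backend contract (`train` / `predict` / `fine_tune`; `predict` returns one
per-organ foreground-probability map in [0,1]) rather than a specific deep
network. Training-protocol constants are fixed in `TrainConfig`: SGD with
momentum 0.9, weight decay 5e-4, batch size 1, 40 epochs, base learning
rate 1e-3 under the "poly" schedule lr(i) = base·(1 − i/max_iter)^0.9 with
max_iter = epochs × images. Augmentation (`AugmentConfig`) applies identical
random scaling (0.5–1.5), rotation (±5°) and cropping (crop side 75% of the
image by default; no crop size is prescribed upstream) to image and masks,
masks resampled nearest-neighbor.

The bundled **reference backend** is a multinomial softmax pixel classifier
(6 classes: background + 5 organs; ~100 weights) over hand-crafted features:
intensity at two Gaussian smoothing scales, a gradient-magnitude channel,
seven radial-basis activations of soft HU bands (air, lung, fat,
soft-tissue, myocardial, bone-like), and quadratic centered pixel
coordinates so decision boundaries can be ellipses. It trains with exactly
the protocol above (one image per step, per-class-balanced pixel
subsampling, pixelwise cross-entropy — the loss is unspecified upstream and
chosen here), with the schedule multiplied by a fixed gain of 300 because
the deep-net base rate is far too small for a tiny linear model on
unit-scale features. Prediction post-processes each organ map by keeping the
largest connected component of the thresholded mask; suppressed satellite
pixels get p → 1−p, which leaves every pixel's confidence margin — and hence
U — unchanged. The backend trains on ~50 phantom slices in seconds on one
CPU and reaches mean lung DSC ≳ 0.95 on held-out phantoms. Its known blind
spot: a 2D per-slice model cannot know that an organ is absent from a slice
(e.g., the heart on apical slices), so per-slice false-positive predictions
on organ-free slices are expected and visible in full-pipeline runs.

## The synthetic phantom (`phantom`)

Clinical CT + RT-STRUCT trial data are access-restricted, so the phantom
generates everything the pipeline consumes. Defaults: 128×128 grid, 1 mm
pixels, 3 mm slices, 8 slices/case. Organs are ellipse polygons (64
vertices) in anatomically plausible positions — lungs lateral, heart
medial-anterior (present only on the middle 60% of slices), esophagus
between heart and cord, cord posterior-midline — with HU-like contrasts
(lungs −750, esophagus −120, soft tissue 30, heart 90, cord 300, air −1000,
Gaussian noise σ = 20 HU). Axes scale smoothly along z (0.75 at the organ's
ends, 1.0 mid-span); per-case anatomy is drawn from jittered priors and
rejection-sampled until all organ masks are disjoint (persistent rejection
means the priors force overlap and raises). Truth masks are rasterized from
the polygons, so writing DICOM CT + RT-STRUCT and re-ingesting reproduces
them exactly.

* **Observer contours**: vertices are displaced radially by circularly
  smoothed Gaussian noise; `jitter_sd` (default 2 px) is the raw per-vertex
  sd, and the low-pass filtering (σ = n/16 vertices) both correlates
  neighbors and attenuates the effective boundary displacement to roughly a
  quarter of the raw sd — chosen so that 1 px jitter keeps large-organ DSC
  well above 0.95 while producing non-degenerate (non-zero-variance)
  validation DSC/HD distributions at the default.
* **Injected gross errors** (default rate 10% per (slice, organ), equal
  mix): *missing* (contour deleted), *shifted* (rigid translation 5–10 px),
  *deformed* (anisotropic scale about the centroid; the factor is calibrated
  so the boundary moves 5–10 px — the same absolute grossness as shifts —
  with 30% as the relative floor, because a bare 30% scale of a 4 px organ
  moves its boundary ~1 px, inside observer noise, and would not be a gross
  error), *spurious* (contour copied onto a slice where the organ's truth
  mask is empty; only organs with partial z-extent, i.e. the heart, can
  receive one). Exact labels are returned for every injected error.
* **Synthetic probability maps**: `confidence` inside the truth mask,
  `1 − confidence` outside, optional Gaussian blur and noise — so
  uncertainty scoring and the QA half of the pipeline are testable without
  training.

What the phantom does *not* emulate: real CT texture and artifacts, 3D
anatomical deformation, inter-patient anatomical variation beyond ellipse
jitter, realistic observer bias (systematic over/under-contouring), or
class-imbalanced error rates per organ. Passing the phantom benchmark
therefore demonstrates that the decision machinery — metrics, criteria,
either-rule, detection accounting — behaves correctly on unambiguous gross
errors over observer-level noise; it does not certify performance on
clinical data.

## Benchmark and problem sizes

The standing benchmark (`pipeline.detection_benchmark`, also run by
`scripts/acceptance.py`) uses 20 validation + 20 test phantom cases (8
slices each, 800 test samples), confidence-0.95 probability maps standing in
for a competent model, and the default 10% gross-error rate. Typical results
at seed 1: BA ≈ 0.99, missing-contour sensitivity 1.0, specificity ≈ 0.98,
AUC ≈ 1.0. The full-training smoke runs (`run_all` in tests and
`examples/04`) use 3–4 cases per set and 6–8 epochs; these sizes are chosen
to keep the whole suite fast on a single CPU while leaving every code path
exercised.

## Numerical choices and degenerate inputs

* Zero validation SD yields degenerate criteria (threshold at the mean); a
  warning is emitted and the conformity score floors the SD at 1e-9.
* Ties in selection break deterministically (higher U, then id order); all
  randomness flows from explicit `numpy` generators, and every pipeline
  stage is bit-reproducible given the config except backend training, which
  is seed-reproducible.
* Degenerate polygons (< 3 vertices or zero area) are skipped with a
  warning during rasterization; fewer than 2 usable validation slices for an
  organ is an error naming the organ.
* DICOM intensities are written as int16 with identity rescale; round-trip
  error is below 0.5 HU.

## Limitations

* Criteria remain of the mean ∓ 1.96σ form for every organ; organ-specific
  criterion *shapes* are out of scope.
* The analysis is strictly slice-wise; no volumetric (3D) metrics, no
  RT-DOSE/PLAN handling, no registration.
* The reference backend is a deliberately small model for desk-scale runs,
  not a clinical segmenter; heavy CNN backends plug in via the contract.
* Ensemble or MC-dropout uncertainty and alternative acquisition functions
  (core-set, BALD) are not implemented.
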