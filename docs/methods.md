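# Methods

## Scope and shape

protodbt is a pipeline tool, not a single fitted model: synthetic cohort
generation → ingestion and slice selection → preprocessing/augmentation →
detection fusion/evaluation → prototypical-part classification → metrics.
The classifier is the one model-like component and exposes a
`fit`/`predict`/`explain` surface with a per-epoch training history; the
rest are deterministic transformations with explicit contracts.

## Slice-span model and inter-slice augmentation

A lesion is annotated only on its central slice; it is assumed visible over
25% of the volume's slices in each direction.  We interpret 25% as
`floor(0.25 · n_slices)` whole slices per direction, clipped to the volume —
the conservative rounding that never exceeds the stated fraction.  Within
that span, 7 slices are selected for benign lesions and 9 for cancerous ones
(partially rebalancing the classes), evenly spaced with the rule
`lo + round(i · (hi − lo)/(k − 1))`, rounding ties toward the lower index,
and always including the central slice (the nearest pick is swapped out if
needed).  Spans shorter than the requested count return every slice — the
real-data interaction of short spans with the 7/9 counts is undocumented, so
take-all is this package's choice.

## Preprocessing

Detection path: direct anisotropic resize to a fixed 1280 × 1050 (H × W)
frame, then CLAHE.  Classification path: minimal square crop with side
`max(w, h)`, centered on the box and shifted (never shrunk) into the frame,
resized to 224 × 224 (64 × 64 in the desk-scale studies).  CLAHE is provided
by scikit-image's `equalize_adapthist`; its clip limit is a fraction in
(0, 1] (default 0.01, 8 × 8 tiles) — note this convention differs from the
OpenCV-style absolute clip limit.  CLAHE is exposed as a configurable stage
in both paths (default: detection on, classification off), since reasonable
pipelines differ on where to apply it.  Geometric resampling is bilinear
with reflect padding.

## Offline augmentation plan

The default plan draws, per image: shift ×2 (±0.1 of the side, per axis),
rotation ×10 (±170°), skew ×10 (corner-perspective, magnitude 0.2),
shear ×10 (±10°), flip up-down ×1, flip left-right ×1, global histogram
equalization ×1, brightness ×1 (gain 0.8–1.2), contrast ×1 (gain 0.6–1.5) —
37 draws, all parameters uniform in their ranges, all randomness from one
seed.  Units are interpretations (fraction of side for shift, degrees for
rotation/shear, multiplicative gains), as the plan itself does not state
them.  The "histogram eq." draw is global equalization, not CLAHE
re-application.  Accounting retains originals: n originals → 38 n images.
The pipeline's default evaluation uses non-augmented test crops; augmented
evaluation accounting remains available because the published per-set counts
include augmented validation/test sets.

## Detection fusion and evaluation

Two detectors' per-image predictions are fused greedily in descending-IoU
order; a pair merges when IoU > 0.3 (strict, as stated), fused confidence is
the pair mean, and the higher-confidence member's box is kept (confidence-
weighted averaging available).  Unmatched predictions keep their box at half
confidence — the mean with an absent partner treated as zero; this is an
inference, not a stated rule, but it is the only reading consistent with
lowering the ensemble's evaluation confidence floor from 0.1 to 0.05 "to
render it comparable".  Evaluation matches predictions to ground truth
greedily by descending confidence, one-to-one, requiring IoU > 0.1.  Greedy
matching is a 1/2-approximation of optimal assignment; tests verify exact
agreement with an independent brute-force greedy oracle and the
approximation bound against `scipy.optimize.linear_sum_assignment`.
Matching is per-slice: each exported slice carries its own ground-truth box.
Reviewer-accepted false positives are reclassified as true positives backed
by new ground-truth findings (TP += k, FP −= k, FN unchanged), which can
only raise recall and precision.

## Prototypical-part classifier

Similarity `log((d²+1)/(d²+ε))` with ε = 10⁻⁴ (configurable); strictly
decreasing in d² for any ε ∈ (0, 1).  Default 5 prototypes per class.
Loss weights default to λ_clst = 0.8, λ_sep = 0.08, with cross-entropy class
weights inversely proportional to class frequency.  The last layer is
initialized +1 own-class / −0.5 cross-class and trained with a 2-logit
softmax cross-entropy; for binary output the positive-class sigmoid is the
equivalent reading.  The backbone is pluggable; the default is a compact
3-block CNN (3×3 conv → ReLU → 2×2 max-pool; 16/32/32 channels) plus a 1×1
sigmoid add-on bounding the latent space in (0, 1), giving an 8 × 8 × 24
latent grid for 64 × 64 crops.  The whole network, including backprop, is
written in NumPy (im2col convolutions, Adam): at desk scale this is fast
(seconds per epoch), exactly reproducible, and auditable line by line.

Training phases: warm-up (prototypes + add-on; backbone frozen), joint
(everything but the last layer), projection, last layer only (lr 10⁻²
vs. 2 × 10⁻³ elsewhere; batch size 16).  Projection snaps each prototype to
its nearest same-class training patch (squared Euclidean), records
provenance (image, grid cell, pixel rectangle), and is idempotent.  Pruning
removes prototypes whose k = 6 nearest training patches are less than 50%
own-class, always retains the highest-purity prototype per class, and
re-optimizes the last layer; k and the threshold are this package's
defaults, as no published values exist.

A latent cell maps to the input rectangle obtained by uniform upsampling of
the grid (cell side = input side / grid side) — the standard receptive-field
approximation used for prototype visualization.

Explanations default to the top-k most activated prototypes **of the
predicted class** (the case-based-reasoning presentation: "cancer, because
these patches look like these cancer prototypes"); `scope="all"` ranks all
prototypes instead, which is useful for inspecting cross-class activations.

## Synthetic data

The generator emulates the geometric and intensity structure the pipeline
assumes, not breast physics: background is a Gaussian-smoothed random field
(σ = 8 px, mean gray 90, amplitude 35) plus per-slice Gaussian noise
(σ = 6); lesions are additive bright blobs (gain = contrast × background
level, default contrast 0.9) present exactly over the slice span, fading
linearly to 20% at the span edges and zero outside.  Benign margins are
smooth ellipses (axis ratio 0.75–1); cancerous margins superpose random
radial harmonics (orders 3–8, amplitudes 0.08–0.22) and 4–7 Gaussian
spiculations.  The margin-roughness statistic perimeter²/area separates the
classes stochastically; this proxy is the package's own choice, since no
published lesion-appearance statistics exist.  Bounding boxes are tight
boxes of the thresholded (0.5) footprint.  Cohorts assign
`round(class_ratio × total)` benign scans by seeded shuffle (default ratio
0.62, matching the study cohort's 124/76 allocation at 200 scans).  The
default cohort is 100 patients × 2 scans of 40 × 160 × 128 volumes.
Passing tests on this synthetic cohort demonstrates pipeline correctness —
spans, accounting, fusion, matching, training mechanics, provenance — not
clinical performance: real DBT lesions are far less separable than the two
synthetic morphologies, and real backgrounds contain structured anatomy the
random field lacks.

## Splits

Patient-level nested 80-20: 20% of patients (rounded to nearest) to test,
then 20% of the remainder to validation — 64/16/20 for 100 patients.
Rounding is to the nearest integer with test computed first; the seed is
stored in the assignment for provenance.

## Desk-scale study sizes

The canonical classification study trains on 120 crops (64 × 64, balanced)
and evaluates on 40 held-out crops with a 3/8/6-epoch schedule; the
detection study uses 40 synthetic scans and two simulated detectors with
complementary misses (hit rates 0.70/0.65, jitter 15%/10% of box size,
background false-positive rates 1.5/0.4 per image).  These sizes keep each
study in the tens of seconds while leaving clear margins on the properties
tested (held-out balanced accuracy > 0.85; ensemble recall above both single
models).

## Numerical choices

Metric ratios with zero denominators are reported as `None`, never 0.
auROC is the rank-based Mann–Whitney area with ties counting 1/2.  Printed
metric values are rounded half-to-even in decimal after suppressing binary
float noise (so the exact tie (0.67 + 0.74)/2 = 0.705 prints as 0.70 rather
than being pushed to 0.71 by its floating-point representative).  IoU is
clamped to [0, 1] against the epsilon overshoot of `(x + w) − x` arithmetic;
zero-area boxes yield IoU 0 with a warning.  All slice and pixel coordinates
are 0-based, boxes half-open `(x, y, w, h)`.

## Known limitations

No anatomical realism in the generator; no FROC analysis; no non-maximum
suppression (assumed done by the detectors); DICOM support covers plain
multi-frame stacks only; the NumPy network is not meant for full-resolution
training — the backbone contract accepts any image→latent-grid map if a
larger extractor is needed.
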