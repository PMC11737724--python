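# Methods

## Scope and model overview

`dermlesion` implements a three-stage dermoscopic analysis pipeline — hair
removal, lesion segmentation, benign/malignant classification — with a
synthetic data generator that gives every stage exact ground truth. The
pipeline applies hair removal once at ingest; both the segmenter and the
classifier consume the cleaned image. The classifier sees the lesion crop:
the tight bounding box of the (predicted or ground-truth) mask padded by
10% per side, with pixels outside the mask zeroed, converted to grayscale
and bilinearly resized to the extractor's patch side.

## Hair removal

The stage assumes hair appears as thin, dark, roughly linear strands with
strong local gradient contrast. Steps and defaults:

| parameter | default | meaning |
|---|---|---|
| `canny_low`, `canny_high` | 30, 90 | hysteresis thresholds on the 0–255 gradient scale |
| `canny_sigma` | 1.0 px | Gaussian smoothing before gradient estimation |
| `bright_cutoff` | 200 | gray level above which pixels are excluded (specular highlights are not hair) |
| `close_radius`, `erode_radius` | 2, 1 px | disk structuring elements; closing bridges the double edge of a strand, erosion removes isolated responses |
| `hough_threshold` | 8 votes | probabilistic Hough accumulator minimum |
| `min_line_len`, `max_line_len` | 10, 0.9·max(H,W) px | candidates outside this band are discarded |
| `dilate_radius` | 2 px | expansion of the rasterised line mask to cover strand width |
| `inpaint_window` | 5 px | odd side of the median neighbourhood |

None of these thresholds is prescribed by the procedure itself; the
defaults were fixed by a 20-image pilot on the synthetic stroke suite
(5 strokes per 64×64 image), where they reach mean hair-pixel recall 0.88
at mean precision 0.46. Grayscale conversion uses the Rec. 601 weighting
(0.299 R + 0.587 G + 0.114 B); any fixed convex weighting would behave
equivalently.

Median inpainting fills boundary-inward: each pass fills every masked pixel
with at least one known neighbour in its window, per channel, using donors
known at the start of the pass; refilled pixels become donors in later
passes. The median of an even donor count is the usual midpoint (average of
the two central order statistics) — chosen to match the standard numpy
convention, and mirrored exactly by the brute-force oracle in the tests. A
mask covering the whole image is an error (no donors). Pixels outside the
mask are returned bit-identical.

The probabilistic Hough transform samples edge points at random; a single
integer seed (default 0) is threaded through `remove_hair` and the CLI.

## Segmentation network

The encoder–decoder follows the ResUNet++ layout: a residual stem, three
encoder stages (squeeze-and-excitation gating followed by a stride-2
pre-activation residual unit), an ASPP bridge, three decoder stages
(nearest-neighbour 2× upsampling, additive attention over the encoder skip,
concatenation, residual unit), a second ASPP, and a 1×1 convolution with
sigmoid producing per-pixel lesion probabilities.

Design choices where the layout was genuinely open:

- **Residual vs dense blocks.** Encoders/decoders use residual units with
  SE gating by default; the dense convolutional block
  (x_i = H(concat(x_{i−1}, Conv(x_{i−1}, k))), H = BN + ReLU) is
  implemented, unit-tested, and swappable into the encoder via
  `use_dense_blocks`.
- **Upsampling** is nearest-neighbour resize followed by convolutional
  fusion. Transposed convolution was considered as an alternative and not
  implemented; nearest-neighbour avoids checkerboard artifacts and keeps
  the op set small.
- **Filter counts** default to (32, 64, 128, 256) stem-to-bottleneck and
  are configurable; desk-scale runs use (8, 16, 32, 64).
- **ASPP rates** default to (1, 2, 4); the dilated 3×3 branch at rate r has
  effective receptive field 1 + 2r per axis (verified by perturbation probe).
- **Loss** is binary cross-entropy plus soft Dice with equal weights
  (smoothing 1.0); validation Dice (threshold 0.5) selects the retained
  weights, since Dice is the segmentation criterion of record.
- **Resize policy**: inputs are bilinearly resized to the network input
  shape, masks with nearest-neighbour; predicted masks are resized back to
  the native frame with nearest-neighbour.

Input sides must be divisible by 2³ (three downsamplings). Training
defaults mirror the published classifier settings (Adam, learning rate
1e-4, batch size 50, 200 epochs); all are exposed on the estimator.

## Classification

The extractor's architecture is fixed by its published description: seven
3×3 same-padding convolutions (32, 32 | 64, 64 | 128, 128, 128 filters),
three 2×2 stride-2 max-poolings, flatten, two fully connected layers —
twelve layers, grayscale input of side 16, 32 or 48. The fully connected
widths are not prescribed; defaults are fc1 = 256, fc2 = 64, and no test
depends on them. The three patch sides are treated as alternative
configurations, not a multi-scale ensemble.

The softmax head used during extractor training is discarded afterwards;
the random forest (default 100 trees, unlimited depth, seeded) is fitted on
activations from a configurable tap — `fc1` by default, `flatten` (2048
elements at side 32) and `fc2` selectable, since the published description
is ambiguous about which activations feed the forest. Adam, RMSprop and SGD
are all selectable; no optimizer ensemble is formed. An SVM head is out of
scope.

The 80/20 split is stratified by label with ceil/floor rounding and a
warned non-stratified fallback when a class has fewer than two members.
HAM10000-style diagnosis codes map to the binary task as
{mel, bcc, akiec → malignant; nv, bkl, df, vasc → benign}; the table is
configurable because no canonical mapping is prescribed.

## Metrics

Jaccard and Dice are computed per mask pair and macro-averaged over a
dataset. Both are defined as 1.0 when both masks are empty (a perfect
prediction of "nothing"). Malignant is the positive class for sensitivity
and specificity. Ratios with zero denominators are reported as NaN with a
warning, never silently as zero. The identity dice = 2j/(1 + j) holds at
machine precision and is asserted property-wise.

## Synthetic data generator

Each sample is a skin-tone background (default RGB (196, 150, 125)) with a
smooth planar illumination ramp (amplitude 18 gray levels, random
direction), one lesion, optional hair strokes, and per-channel Gaussian
pixel noise (sd 4, clipped to [0, 255]).

The lesion outline is an ellipse in polar form perturbed by
(a) border irregularity — smooth random-phase harmonics (orders 3–8) scaled
by 0.35 × the irregularity parameter, (b) asymmetry — a cos θ radial skew
that shifts mass to one side, and (c) colour variegation — darker tinted
sub-blobs inside the mask. The lesion region is multiplicatively darkened
(factor 0.45), which guarantees every lesion pixel is strictly darker than
the pre-noise background — the property that keeps the segmentation task
learnable by construction. Hair strokes are quadratic Bézier polylines
(3 control points, slight curvature), thickness 2 px, drawn at dark
intensity 35 so the Hough stage can legitimately recover them; strokes may
exit the frame and are clipped.

The label is a deterministic function of the morphology parameters —
malignant iff border irregularity > 0.4 or variegation ≥ 3 or
asymmetry > 0.3 — mimicking the clinical ABC triage criteria. Dataset
sampling draws benign parameters from (irregularity U(0, 0.25), asymmetry
U(0, 0.15), variegation {0, 1}) and malignant from (U(0.55, 0.85),
U(0.35, 0.55), {3, 4, 5}); the gap makes the task separable by a depth-2
decision stump, so classifier tests measure the pipeline rather than task
difficulty. What the generator does **not** emulate: real lesion texture,
ruler/gel artifacts, vignetting, camera noise statistics, and ambiguous
borderline lesions — passing tests therefore demonstrate mechanical
correctness and learnability, not clinical performance.

## Numerical engine and determinism

Both networks run on `dermlesion.nn`, a compact numpy reverse-mode autodiff
engine (float32, NHWC): convolution is implemented as k² shifted
BLAS matrix products (stride/dilation/same/valid), pooling as block
argmax with exact gradient scatter, batch normalisation with momentum-0.9
running statistics. Gradients of every op are verified against central
finite differences. Weight initialisation is He-normal from a seeded
generator. Training is a pure function of the estimator seed — weight
init, splits, and batch order all derive from it — and is bit-reproducible
on one device; per-stage seeds derive deterministically from one global
pipeline seed.

## Desk-scale problem sizes

The test suite trains the segmenter on 60 synthetic 64×64 images for 30
epochs with filters (8, 16, 32, 64), learning rate 1e-3, batch 4 (best
validation Dice ≥ 0.85, typically ≈ 0.99), and the classifier on 300
synthetic 32×32 crops for 20 epochs at learning rate 1e-4, batch 50
(forest validation accuracy ≥ 0.9, majority baseline 0.5, forest within
0.05 of the softmax head). These sizes are the package's chosen desk-scale
benchmark; full-dataset clinical training is out of scope.

## Known limitations

- The hair model is straight-to-slightly-curved; tightly coiled hair would
  defeat the line-based detector.
- Median inpainting is local; it blurs texture under wide masks compared to
  exemplar- or diffusion-based methods.
- The numpy engine targets clarity and determinism, not throughput; it is
  suited to desk-scale inputs, not full-resolution clinical training.
- Benchmark accuracies reported for clinical datasets are not reproduced
  here; they require full downloads and GPU-scale training.
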