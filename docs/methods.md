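# Methods

## Problem and model

The package segments tumor tissue in 2D RGB brain-MRI slices (256×256×3,
8-bit) with single-channel binary ground-truth masks, the export format of
the public lower-grade-glioma (LGG) MRI collection.  The segmentation
network is an encoder–decoder hybrid:

- **Bottom-up pathway.** A U-Net contracting path: a full-resolution stem of
  two 3×3 conv–BN–ReLU layers, then four stages of 2×2 max-pool followed by
  two 3×3 conv–BN–ReLU layers, with channel widths doubling per scale
  (64 → 1024 by default).  The four post-downsampling scales (input/2 …
  input/16) form the feature pyramid.
- **Top-down pathway.** Each pyramid level is reduced to a common width by a
  lateral 1×1 convolution (128 channels by default).  Starting from the
  coarsest level, the running map is upsampled ×2 with nearest-neighbor
  interpolation and added element-wise to the next lateral map.  Each merged
  level is refined by two 3×3 convolutions.
- **Fusion head.** All refined levels are upsampled (nearest-neighbor, exact
  powers of two) to the finest pyramid resolution and concatenated — 4
  levels × 128 channels = 512.  A 3×3 convolution with batch normalization
  and ReLU fuses them; a 1×1 convolution produces single-channel logits,
  which are bilinearly upsampled to the input resolution and passed through
  a sigmoid.

The baseline for comparison is a classical U-Net with the same encoder and
an expanding path of nearest-neighbor upsampling + 1×1 reduction, skip
concatenation, and two 3×3 conv–BN–ReLU layers per stage.

Design points that were genuinely open and how they were resolved:

- *Pyramid taps.*  The pyramid uses the four post-downsampling scales and
  skips the full-resolution stem; four levels at 128 lateral channels give
  exactly the 512-channel fusion width of the architecture.
- *Fusion resolution.*  Levels are concatenated at the finest pyramid level
  (input/2), not at input resolution; the final bilinear upsample restores
  input size.  Fusing at full resolution would quadruple the cost of the
  most expensive convolution for marginal benefit.
- *Interpolation.*  Top-down merges use nearest-neighbor upsampling; the
  final logit upsample is bilinear.
- *Residual encoder.*  Identity shortcuts around encoder blocks exist as an
  option (`ModelConfig.residual_encoder`) but are off by default.
- *Head initialization.*  The head bias is initialized to −2 so untrained
  predictions start near background (sigmoid(−2) ≈ 0.12).  Tumor pixels are
  a small minority, and starting from a background prior both matches the
  class frequencies and strengthens the early Dice gradient on foreground;
  the same trick is standard in one-stage detection heads.

## Loss and metrics

Training minimizes the smoothed Dice loss

    L = 1 − (2|A∩B| + ξ) / (|A| + |B| + ξ),   ξ = 100 by default,

where A is the predicted pixel set and B the reference set.  For soft
predictions, |A∩B| = Σ p·g and |A| = Σ p (the differentiable relaxation).
ξ keeps the loss defined when both masks are empty ((0+ξ)/(0+ξ) = 1, loss
0); ξ = 100 is unusually large for a smoothing constant but is kept as the
protocol value and is configurable.  The loss pools all pixels of a batch
into one Dice term by default (stabler gradients); a per-image mode is
available.  An optional compound Dice + weighted-BCE loss exists and is off
by default.

Evaluation uses hard masks (threshold 0.5): DSC = 2|A∩B|/(|A|+|B|),
Jaccard/IoU = |A∩B|/|A∪B| (= DSC/(2−DSC)), and pixel accuracy
(TP+TN)/(TP+TN+FP+FN).  When both masks are empty, DSC and Jaccard are
defined as 1 (perfect agreement).  Reported DSC/Jaccard are per-image means
(pooled-over-pixels variants are also computed); accuracy is the global
pixel ratio.  The aggregation convention is explicit because published
values rarely state it.

## Data pipeline

Images load as uint8 RGB; the mask shares the image's file stem plus a
configurable suffix (`_mask` in the public collection).  Preprocessing:
global normalization (÷255 to [0,1]); mask thresholding at 0.5 to strict
{0,1}; deletion of tumor-free slices (class-balance filtering); random
70/20/10 train/validation/test split.  Validation/test sizes are
round(n·f) with the remainder to train, so sizes are deterministic.  The
split is record-level by default; a patient-level grouping option assigns
whole patients to one partition, because slice-level splitting of a real
cohort leaks patient appearance across partitions.  Note: applying 70/20/10
to a 1373-slice cohort gives 961/275/137; the published counts for that
cohort (988/247/138) are mutually inconsistent with the stated fractions,
and the stated fractions are what is implemented.

## Augmentation

Nine operations, considered independently per sample in a fixed order:
horizontal shift (0.25), transpose (0.25), vertical shift (0.25), blur
(0.05), random crop (0.05), random rotate (0.5), random resize (0.25),
random flip (0.5), random brightness (1.0).  The bare protocol numbers do
not state their semantics; this package follows mainstream augmentation
tooling: shift and resize parameters are maximum fractional magnitudes drawn
uniformly from ± the range; brightness is the width of a multiplicative
jitter around 1 (factor ∈ [0.5, 1.5], clipped to [0,1] after scaling);
transpose, blur, crop, rotate and flip are application probabilities.
Rotation angles are uniform in ±30°; crops resample a 70–95% window back to
full size; all semantics are config-overridable.  Geometric transforms use
bilinear interpolation for the image and nearest-neighbor for the mask, so
masks remain strictly binary; out-of-frame regions are zero-filled; blur and
brightness never touch the mask.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), batch size 8, up to 150 epochs, learning rate
1e-4, early stopping on the validation Dice loss with patience 10 and
min_delta 1e-4, restoring the best-epoch weights (patience and restoration
are this package's choices; the protocol invokes early stopping without
parameters).  Augmentation applies to training batches only.  A single seed
controls the split, augmentation stream, and weight initialization, making
runs bit-reproducible.

## Numerical engine

The networks run on a compact numpy automatic-differentiation engine written
for this package: float32 NCHW tensors, convolutions as im2col +
BLAS matrix products, reverse-mode gradients for every primitive
(convolution, batch norm, max-pool, nearest/bilinear upsampling,
concatenation, sigmoid/ReLU, soft Dice and BCE losses), and Adam.  All
gradients are verified against central finite differences in the test
suite.  Batch normalization keeps running statistics (momentum 0.1,
eps 1e-5) for inference mode.  Bilinear resizing uses dense separable
interpolation matrices (half-pixel centers), whose transpose gives the exact
adjoint for the backward pass.

## Synthetic phantoms

The generator emulates the statistical structure of the study data so every
module is testable without downloads: an elliptical "brain" (randomized
pose and axes) with smooth Gaussian-filtered texture on a dark noisy
background; per-channel gains (1.0/0.88/0.78) mimicking RGB-exported
multi-sequence MRI; with configurable probability (default 0.35, mirroring
a cohort where roughly a third of slices are positive), 1–3 hyperintense
blobs — ellipses whose radius is modulated by low-order sinusoids, giving
the irregular boundaries that make edge behavior testable.  Blob supports
are clipped to the brain ellipse and the mask is their exact union.  Tumor
pixels are brighter than surrounding brain by a configured contrast
(default +80 on the 0–255 scale), which makes the task learnable at desk
scale.  What the phantoms do **not** reproduce: real MRI noise statistics,
partial-volume and bias-field effects, anatomical context (ventricles,
skull), or ambiguous tumor boundaries.  Passing the phantom benchmarks
therefore demonstrates that the implementation optimizes and generalizes
correctly on data of this structure — not clinical-grade performance.

## Scaled-down experiment sizes

The packaged experiments run on one CPU, so they use 64×64 phantoms and
reduced widths: `ModelConfig.small` (widths 8–128, lateral 16) for training
runs and `ModelConfig.medium` (widths 16–256, lateral 32) for the
single-batch memorization probe.  Cohort size is 200 phantoms
(140/40/20 after the 70/20/10 split).  For these reduced runs the learning
rate is 1e-3, selected — as in the full-scale protocol, which chooses
between 1e-3 and 1e-4 by learning curve — from the same range at this
scale; the full-width default remains 1e-4.  Training runs cap epochs at
30, comfortably past where early stopping engages at this scale.

On the default (easy, high-contrast) phantoms both architectures segment
well, and the baseline U-Net can match or exceed the hybrid — e.g. the
acceptance script at seed 1 reports held-out DSC 0.92 (hybrid) vs 0.97
(U-Net).  The phantoms do not reproduce the multi-scale, low-contrast edge
detail on which pyramid fusion is argued to help, so the CPU-scale
comparison validates correctness of both implementations, not the relative
ranking on real MRI; the generator's "hard" settings (lower
`tumor_contrast`, smaller radii) exist for stress comparisons.

## Known limitations

- The engine is CPU-only and single-threaded; full-width training at
  256×256 is out of reach (hours per epoch), which is why the packaged
  experiments are scaled down.
- Only binary (single-foreground-class) segmentation is supported; no
  surface-distance metrics (Hausdorff, ASSD).
- 2D slices only; no DICOM/NIfTI volume handling.
- Checkpoints store raw arrays (.npz) keyed by parameter path; loading
  requires reconstructing the same architecture config.
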