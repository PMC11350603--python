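# Methods

## Problem and model

`shootcount` estimates per-image object counts (conifer new shoots) from
point-annotated RGB images by density estimation.  Ground truth for a
labeled image is a density map in which every annotated point carries unit
mass; the count is the map's integral.  A convolutional network regresses
the density map at 1/8 input resolution and, in parallel, classifies the
image into one of C density classes.  Training is semi-supervised in the
mean-teacher style: the student is trained by gradient descent on
L = L_L + L_U; the teacher is an exponential moving average (EMA) of the
student and supplies the targets for the unlabeled consistency terms.

Assumptions worth stating explicitly:

- Objects are small relative to the image and roughly isotropic, so a
  Gaussian kernel per point is an adequate mass model, and a 1/8-resolution
  density grid retains the count information (sum-preserving block pooling
  makes this exact for the targets).
- Scene scale is homogeneous (top-down crown imagery): no perspective map
  exists and none is modelled; kernel bandwidth adapts only to local
  crowding.
- Unlabeled and labeled images are drawn from the same distribution; the
  consistency loss assumes the teacher's predictions on unmasked views are a
  useful target for the student's masked views.

## Density maps

Geometric adaptive kernel: σᵢ = β · (mean distance of point i to its k
nearest annotated neighbours), defaults k = 3, β = 0.3 — the convention
established for congested-scene counting.  Images with a single point (no
neighbour distance) fall back to a fixed σ = 4 px.  Each kernel is
evaluated on a ±4σ window and renormalised to unit mass *inside* the
canvas, so border objects still count exactly once; conservation
(|∑D − count|/count < 10⁻²) is a tested invariant and in practice holds to
machine precision.  The per-pixel renderer is verified against a dense
full-canvas oracle evaluation to 10⁻⁶.

Density classes: the classification target is per image, the class of its
count under C = 5 right-open bins whose edges sit at the quantiles
(1/C … 1) of the labeled-training counts.  Quantile edges guarantee
non-degenerate classes for any dataset.  Whether the density class should
be per image or per patch is genuinely open; per-image is the package's
choice and the binning is fully configurable.

## Losses

- Segmentation mask M^gt = 1(D^gt > ε), ε = 10⁻³, restricts the structural
  term to regions that actually carry mass.
- SSIM uses the literature-standard 11 × 11 Gaussian window (σ = 1.5) over
  valid positions, with stabilisers Z₁ = 0.01, Z₂ = 0.03 added directly.
  On grids smaller than the window (the pyramid's coarse levels of an 8 × 8
  head output) the window shrinks to the largest odd size that fits; at
  size 1 the local variances vanish and SSIM degenerates to a mean
  comparison, which is the only meaningful content at that scale.
- The structural loss SL averages 1 − SSIM over a K = 3 level average-pool
  pyramid (scales 1, 1/2, 1/4).  SL ∈ [0, 2]; SL = 0 iff the masked maps
  agree at every level.
- L_TV = ½ · count(D^gt) · ‖D^gt/‖D^gt‖₁ − D^P/‖D^P‖₁‖₁ per image —
  invariant to positive rescaling of the prediction, it penalises where the
  mass sits.  Both-zero maps define loss 0; the normalising denominators
  carry a 10⁻¹² floor.  Weight λ₁ = 0.01.
- Classification uses cross-entropy with the probability floored at 10⁻¹²
  before the log.
- Unlabeled regression consistency L_RU: smooth-L1 (β = 1) between student
  and detached teacher density maps, restricted to the masked-patch
  footprint block-reduced to the 1/8 grid; per image it is the **sum over
  masked patches** of the patch-averaged smooth-L1 (so more masking means
  proportionally more signal), then averaged over the batch.  The
  classification consistency L_CU compares the two per-image class
  distributions once with smooth-L1 — the distributions carry no patch
  index, so a per-patch sum would be meaningless for them.
- All analytic gradients are tested against central finite differences.

## Masking and augmentation

Patch-aligned random masking with patch size 16 and ratio 0.1 as defaults;
the number of masked patches is round-half-up(ratio × patches), which keeps
the realised ratio closest to nominal across patch-grid sizes.  Masks are redrawn
every iteration; the fill value is the dataset-scale mean intensity (0.5 on
the unit scale) to avoid injecting dark pseudo-objects.  Only unlabeled
images are masked, and only the student sees the masked view.  Photometric/
geometric augmentation: brightness ±20%, horizontal flip p = 0.5, rescale
in [0.8, 1.2] with crop; point coordinates follow the pixel transform and
points leaving a crop are dropped.  Flips reuse the cached density map
(flipping is an isometry, so adaptive bandwidths are unchanged).

## Network

"Improved VGG19": the printed stage shapes (H/8 × W/8 × {256, 512, 512})
force pooling to stop after stage 3, so stages 4–5 use dilation-2
convolutions at 1/8 resolution.  The second fusion needs equal channel
counts, so the 512-channel AFF output is projected to 256 channels by a 1×1
convolution before fusing with the stage-3 map (a declared convention).  MS-CAM bottleneck reduction is 4.  MDC dilations are
(1, 2, 3): the smallest set whose union of taps covers a contiguous window
with no gridding holes (a tested property).  The regression output passes a
ReLU because densities are nonnegative by definition.  Weights are
He-normal with a small positive bias (keeps thin-profile ReLUs alive);
loading externally pretrained backbone weights is not implemented.

The tensor substrate is a compact reverse-mode autodiff engine over NumPy
(float64) written for this package: dilated conv2d via strided windows,
2×2 max/average pooling, the elementwise algebra the losses need, and Adam.
Everything is finite-difference tested; float64 keeps those checks and the
SSIM pyramid clean at the modest problem sizes involved.

## Training

Student steps use Adam; the full profile mirrors the reference settings
(crop 256, batch 16, 500 epochs, lr 10⁻⁵, weight decay 10⁻⁴, EMA α = 0.99
ramped linearly over the first 500 iterations).  The teacher is evaluated
and checkpointed (mean-teacher convention; a config switch selects the
student instead).  Teacher parameters never receive gradients — a tested
invariant.

The reduced desk profile exists so the identical code path runs on one CPU
core in minutes: 64 px images, width multiplier 1/8, stage depths
(1, 1, 2, 2, 2), batch 4, Adam 10⁻³ (conventional for a thin network; the
full-profile 10⁻⁵ would barely move in a few hundred steps), and EMA
α = 0.95 with a 20-iteration ramp.  The shorter EMA time constant is a
deliberate desk-scale calibration: at α = 0.99 the teacher's half-life
(~69 steps) is a large fraction of a few-hundred-step run, so the teacher
would only ever lag the student; α = 0.95 keeps the averaging window a
comparable fraction of the budget as in the full 500-epoch schedule.

## Synthetic data

The generator emulates the statistical structure of top-down crown imagery:
8-divisible canvases, three procedural background classes (road: smooth
grey with streaks; soil: brown mid-frequency clumps; grass: green
high-frequency texture), and shoots as anisotropic bright green-yellow
Gaussian bumps (σ 1.5–3 px at full scale) with uniform-random positions and
per-image counts uniform in a configurable range.  At the reference
1024 × 768 canvas the default count range is 80–246; smaller canvases scale
the range by area so local density stays realistic.  Everything is
deterministic in (spec, seed).

What it does **not** emulate: real shoot shape and colour statistics (no
published appearance model exists to calibrate against), occlusion by
branches, perspective or illumination gradients, and spatial clustering of
shoots (positions are uniform).  Passing tests on this data therefore
demonstrate that the pipeline's mechanics — kernels, masking, losses,
EMA, optimisation — behave correctly, not that the trained model transfers
to field imagery.

## Desk-scale directional experiment

Conditions, fixed once: 64 × 64 scenes with counts 8–20 (strict area
scaling of the reference range would give ~1 shoot per image and make MAE
comparisons vacuous; 8–20 keeps the task non-trivial while blobs remain
sub-cell at the 1/8 grid), blob σ 1–2 px, grass background; 55 training
images of which 5 are labeled (select_labeled at 10%), 10 validation
images; 30 epochs × 10 steps for both arms; the mean-teacher arm evaluates
its teacher, the supervised-only arm its student; best-validation model per
arm; 3 seeds, median compared.

The property checked is directional and stochastic: the mean-teacher median
validation MAE is no worse than the supervised-only median.  At this scale
the margin is small (fractions of a shoot) and individual seeds can go
either way; the experiment is a sanity check that the consistency machinery
helps rather than hurts, not a reproduction of full-scale benchmark
improvements, which would require GPU-scale training on real imagery.

## Known limitations

- No pretrained backbone: counting accuracy at full scale would benefit
  from ImageNet initialisation, which this package does not ship.
- The NumPy engine is single-threaded BLAS-bound; the full profile is
  impractically slow for real 500-epoch training and exists as a faithful
  configuration surface, not a performance claim.
- Per-image (not per-patch) density classification is a declared
  convention; a per-patch variant would need its own head geometry.
- The TV term follows the count-weighted normalised-L1 formulation of the
  optimal-transport counting literature; other published variants differ.
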