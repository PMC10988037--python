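# Methods

## Problem and model

Hepatic vessels occupy a tiny, branching, low-contrast fraction of an
abdominal CT volume — typically well under 2 % of the voxels inside the
liver — which makes their segmentation a severely class-imbalanced,
fine-structure problem. `vesseg` implements a modified 3-D V-Net for this
task, with three architectural changes relative to the original
five-level V-Net:

1. **Dilated deepest stage.** The fifth encoder level is removed. The
   fourth level instead applies three dilated 3×3×3 convolutions with
   rates r = 3, 4, 5, whose effective kernels follow
   `kd = k + (k−1)(r−1)` = 7, 9, 11 voxels. Arranged in series (the
   default) their receptive fields compose to 7+9+11−2 = 25 voxels per
   axis at 1/8 resolution, recovering the field of view the removed
   downsampling stage would have provided without the further loss of
   spatial detail. A parallel arrangement (branch outputs summed) is
   available via `dilated_arrangement: parallel`.
2. **Pyramid-convolution skip blocks.** Every skip connection passes
   through a block with parallel 3³/5³/7³ convolution branches, an
   identity shortcut, and a trailing 1×1×1 convolution. The branch merge
   is element-wise summation; because the merge is a sum, the block is
   evaluated as a single 7³ convolution whose kernel is the zero-padded
   sum of the three branch kernels — arithmetically identical, roughly
   1.4× cheaper, and gradients still flow to each branch's own
   parameters through the padding graph.
3. **Multi-resolution deep supervision.** The three upper decoder levels
   (full, 1/2, 1/4 resolution) each carry an independently initialised
   1×1×1 reduction head; the deepest (1/8) level has none. Path logits
   are fused coarse-to-fine by trilinear 2× upsampling and element-wise
   addition, and the objective is the unweighted sum
   `L_total = L_all + Σ_{d=1..3} L_d`, where `L_all` scores the fused map
   and each `L_d` scores one path against a label downsampled to its
   resolution.

Everything else follows V-Net convention: 3×3×3 kernels, PReLU
(per-channel slope, init 0.25), residual stages of depth 1/2/3 per
encoder level (mirrored in the decoder), 2×2×2 stride-2 convolutions for
downsampling, 2×2×2 stride-2 transposed convolutions for upsampling,
channels base·(1,2,4,8), dropout p=0.5 closing every residual stage, and
a two-channel softmax output. Input extents must be divisible by 8;
`predict` pads symmetrically (edge mode) and crops afterwards so its
output grid always matches its input.

## Losses

The training objective is selectable by name (`tversky | dice | gdl |
bce | focal`); all five share one interface exposing the loss value and
its analytic per-voxel gradient with respect to (p0, p1).

The Tversky index with foreground probability p0, background p1, and
binary labels g0/g1 is

    T(α, β) = Σ p0·g0 / (Σ p0·g0 + α Σ p0·g1 + β Σ p1·g0),

and the loss is 1 − T. α weights false positives, β false negatives;
α = β = 0.5 recovers soft Dice exactly, and the defaults α = 0.3,
β = 0.7 trade precision for the sensitivity that thin terminal branches
need. The implementation differentiates this expression directly:

    ∂T/∂p0_i = (g0_i·D − N·(g0_i + α·g1_i)) / D²
    ∂T/∂p1_i = −β·g0_i·N / D²

with N and D the smoothed numerator and denominator. Centred finite
differences arbitrate correctness (tested to 1e-4 relative error on
hundreds of random instances). A smoothing constant ε = 1e-5 is added to
N and D so empty-foreground patches yield a finite zero loss rather than
0/0.

Generalised Dice uses the standard squared-reciprocal class weights
w_c = 1/(Σ g_c)². Focal loss defaults to γ = 2 with no class weight and
reduces exactly to mean binary cross-entropy at γ = 0. Batch reduction is
the mean (batch size is 1 throughout, after the published recipe).

## Preprocessing

Order: clip → resample → normalise. Intensities are clamped to the
0–400 HU liver window; volumes are resampled to isotropic 1×1×1 mm
(order-3 spline for images, nearest-neighbour for masks so they remain
binary; output shape = round(shape·spacing/target)); then each volume is
z-scored to zero mean, unit variance. Normalising after resampling keeps
the statistics those of the grid the network actually sees; statistics
are per-volume. A liver region of interest is built by dilating a liver
label 20 mm outward per axis with a box structuring element (a
physical-ball option exists but is not the default), and image + label
are cropped to its bounding box with the offset recorded for reinsertion.
The only augmentations are seeded axis flips applied jointly to image
and label.

## Post-processing

Connected components of the predicted mask are labelled under
26-connectivity (thin oblique vessels fragment under face-only
6-connectivity, which remains available) and components with volume
strictly below 180 mm³ are removed; a component of exactly 180 mm³ is
kept. Volume is voxel count × voxel volume from the grid spacing, so the
threshold is spacing-aware. A threshold of 0 is an explicit no-op;
negative thresholds are rejected.

## Metrics

Dice, accuracy, sensitivity and specificity derive from exact voxel
confusion counts; Dice is additionally computed by the independent
set-overlap route 2|P∩G|/(|P|+|G|) as a cross-check, and the two routes
agree exactly. Metrics with zero denominators are reported as undefined
(NaN) and flagged in the report rather than coerced to a conventional
value. Cross-validation aggregation reports mean ± sample (n−1) standard
deviation per metric.

## Synthetic phantoms

The phantom generator reproduces the statistical structure the method
targets, not CT physics: a binary branching tree of straight tube
segments with geometrically tapering radii (child radius = parent ×
taper, taper 0.7 by default) is rasterised as capsules (a voxel is
foreground iff its centre lies within a segment's radius of the
segment's axis, so tubes carry hemispherical caps), and intensities are
two Gaussians — parenchyma at 80 HU, vessels 120 HU brighter, both with
σ = 20 HU noise, all inside the 0–400 HU window. The default native grid
is anisotropic (1×1×2 mm) so the resampling path is exercised. Dataset
generation retries with a rescaled root radius until each volume's
foreground fraction lands within [0.25×, 4×] of the 1 % target, and
derives per-volume seeds as master + index.

What the phantoms deliberately lack: realistic hepatic topology (no
portal/hepatic tree distinction), contrast-phase effects, organ context,
partial-volume blur, and scanner noise correlation. Passing the
end-to-end tests therefore demonstrates that the architecture, losses,
optimisation and evaluation machinery work as specified — not that the
model reaches clinical-grade accuracy on patient CT.

## Numerical backend and determinism

The network runs on a compact reverse-mode autodiff engine over float32
numpy arrays written for this package: convolutions are im2col + BLAS
GEMM evaluated in bounded slabs with pooled scratch buffers, the 2×2×2
stride-2 transposed convolution is a single GEMM plus interleave, and
trilinear resizing uses the half-voxel-centre convention (a factor-2
downsample is then exactly 2×2×2 block averaging, which is also how
supervision labels are downsampled before re-thresholding at 0.5, ties
to foreground). All randomness — weight init, dropout, patch sampling,
fold assignment, phantom growth — flows from explicit seeds, so a config
+ seed pair reproduces loss curves and metrics bit for bit in
single-threaded execution. Checkpoints round-trip through `.npz` with
the configuration embedded.

## Desk-scale study conditions

The shipped end-to-end runs use nine 48³ isotropic phantoms at ~1 %
foreground, whole-volume 48³ patches, Tversky(0.3, 0.7), Adam at
lr 1e-4, batch 1, dropout 0.5, deep supervision on, and a base width of
4–8 channels (the package default is 16, the original V-Net convention;
base width is a config knob and the thin variants keep the full
architecture — the channel schedule stays base·(1,2,4,8)). Under these
conditions held-out Dice crosses 0.6 after roughly 75 optimisation steps
and plateaus near 0.75–0.78 by 150–300 steps; the determinism contract
is checked by re-running the same configuration twice and requiring
identical loss curves and validation metrics.

## Known limitations

* The intensity model makes phantom vessels nearly threshold-separable;
  convergence speed and attainable Dice on real CT will differ
  substantially.
* The published training recipe (lr 1e-4, batch 1) is kept even where a
  larger rate would converge faster at desk scale.
* Whole-volume inference only; no sliding-window tiling for volumes that
  exceed memory.
* The series arrangement of the three dilated convolutions and the
  additive pyramid/fusion merges are design choices where the
  architecture description admits alternatives; both alternatives are
  exposed as config switches (`dilated_arrangement`, and
  concat-style fusion is intentionally not implemented — only additive
  fusion keeps the fusion step linear).
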