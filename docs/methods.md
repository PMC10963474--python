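# Methods

## The segmentation problem

Short-axis cine cardiac MR studies are segmented into three structures at
the two extreme cardiac phases (end-diastole, ED, and end-systole, ES):
the right-ventricular blood pool (label 1, RV), the left-ventricular
myocardium (label 2, Myo) and the left-ventricular blood pool (label 3,
LV), with 0 as background — the ACDC labeling convention. The heart
occupies a small fraction of each slice, its borders are blurred by motion
and partial-volume effects, and surrounding tissue can share the blood
pool's intensity, so a single-stage segmenter wastes capacity on
background and is distracted by look-alike tissue.

`catseg` implements a two-stage cascade:

1. **Coarse localization.** A slice-wise semantic segmentation network
   predicts all four classes per slice. Its encoder is a SqueezeNet-style
   stack — a convolutional stem followed by nine *fire modules*
   (squeeze 1×1 → parallel 1×1 / 3×3 expansions, concatenated)
   interleaved with three 2×2 max-pooling stages, giving output stride 8.
   A modified atrous spatial pyramid pooling (ASPP) block merges context
   at dilation rates d = 4, 8, 12: one 1×1 branch, one depthwise-separable
   3×3 branch per rate (padding = rate preserves size), and a max-pooling
   branch restored by nearest-neighbour upsampling — five parallel
   branches concatenated and projected by a 1×1 convolution. The decoder
   fuses one low-level encoder feature (after the first pooling stage)
   with the 4×-upsampled ASPP output and restores input resolution. The
   union of predicted foreground over all slices, expanded by a margin
   (default 8 voxels) and grown to a minimum size, yields one prismatic
   in-plane ROI box per volume.

2. **Fine segmentation.** A 3D attention residual UNet segments the
   normalized crop. Encoder and decoder are built from full pre-activation
   residual blocks (norm → ReLU → conv, twice, plus an identity or 1×1×1
   projection shortcut); each encoder level after the first downsamples
   in-plane by a strided convolution inside its first block; decoder
   levels upsample by transposed convolution. Every skip connection passes
   through a spatial attention gate: the skip feature is compressed
   (strided 1×1×1 conv) to the grid of the gating signal — the decoder
   feature one level below — summed with the projected gate, rectified,
   reduced to one channel, linearly resampled to the skip grid and
   squashed by a sigmoid; the resulting map α ∈ (0,1) multiplies the skip
   feature voxel-wise. A network of depth *d* has *d − 1* gates; setting
   `attention_enabled = False` replaces every gate by a pass-through
   (α ≡ 1), recovering a plain residual UNet for ablations.

Predicted crop labels are pasted back through the exact recorded inverse
of the crop geometry; every voxel outside the ROI is background. ED and ES
are processed independently through the same weights.

Evaluation follows the usual overlap scores per structure and phase,

    DSC = 2·TP / (2·TP + FP + FN),   IoU = TP / (TP + FP + FN),

pooled over the voxels of a volume and macro-averaged across patients
(micro-averaging is a flag). When both regions are empty the score is 1 by
convention; when exactly one is empty it is 0. The identity
DSC = 2·IoU/(1 + IoU) is property-tested. A stratified patient-level
k-fold harness (both phases of a patient always travel together; per-class
fold counts differ by at most one) supports cross-validated reporting.

## The numerical substrate

No GPU framework is assumed: the networks run on a compact reverse-mode
automatic-differentiation engine over NumPy written for this package
(`catseg.nn`). Dense N-D convolution lowers to a single BLAS GEMM through
an im2col buffer (numba-accelerated data movement, with a pure-NumPy
fallback); 1×1 kernels skip im2col; depthwise convolutions use an
offset-loop path. Transposed convolutions use kernel = stride
(non-overlapping). Every fused operation's gradient — convolution
variants, batch normalisation, max pooling, nearest/linear factor-2
resampling, softmax, cross-entropy, soft Dice — is verified against
central finite differences in the unit suite.

## Training recipe

Adam with initial learning rate 1e-3 and L2 weight decay 1e-4; the loss is
voxelwise cross-entropy plus a soft multi-class Dice term over the three
foreground structures (weight 1, config-exposed) — aligned with the DSC
the pipeline is judged on. The learning-rate "decay factor of 0.1 per
epoch" is implemented as time-based decay lr(t) = lr0/(1 + 0.1·t): the
literal reading (multiply by 0.1 every epoch) extinguishes learning within
a few epochs of a 100-epoch schedule and is available via
`literal_step_decay=True`. Splits are patient-level (default 80/20
train/validation); ED and ES samples mix in every batch; the weights from
the best-validation-DSC epoch are kept. All randomness flows from one
integer seed: two runs with the same seed produce bit-identical weights.

The segmenter trains on ground-truth-guided ROI crops (teacher forcing):
the box is derived from each phase's own label map, so localization errors
do not corrupt segmenter training; at inference the box comes from the
localizer.

## The phantom generator

Real cine MR cannot ship with the package, so a synthetic phantom cohort
with the statistical structure of a short-axis study stands in: per slice,
an LV blood-pool disk inside a myocardial annulus with an RV crescent
(an offset disk abutting the epicardium, minus the epicardial disk),
constant across the 10 slices (a prismatic heart), on a 160×160 grid at
(1.5, 1.5, 8.0) mm spacing — slice thickness within the clinical 5–8 mm
range. Five pathology classes modulate geometry through an editable
class-conditional table calibrated to adult anatomy at 1.5 mm/voxel
(normal LV endocardial radius 14–17 voxels ≈ 21–26 mm): DCM dilates the
cavity and weakens contraction, HCM thickens the annulus around a small
cavity, MINF thins a 72° free-wall sector to 60 % thickness and reduces
contraction, and the abnormal-RV class enlarges the crescent. ED is always
at least as dilated as ES.

Intensities are drawn per voxel from tissue-specific normal distributions
(background 60 ± 10, myocardium 110 ± 12, both blood pools 180 ± 15,
arbitrary units), then six distractor blobs per volume — placed off-heart
and drawn from the *blood-pool* distribution so the localizer cannot
succeed by thresholding — modify intensities only, never labels; an
in-plane Gaussian blur (σ = 1.2 voxels) emulates fuzzy borders, and
additive noise (σ = 6) follows. Labels are rasterized before any
corruption, so they are exactly invariant to the intensity pipeline.

What the phantom does *not* emulate: MR physics (coil bias, k-space
artifacts), through-plane tapering toward the apex, full 12–35-frame cine
dynamics, anatomical texture within tissues, and inter-observer label
noise. Passing the end-to-end tests therefore demonstrates that the
architecture, cascade plumbing and training loop can recover known
geometry from confusable intensities — not clinical-grade performance on
real data.

## Problem sizes and the desk-scale study

The published architecture scale (SqueezeNet v1.1 fire ladder; depth-4,
base-32 UNet) is the package default and is what the conformance checks
build. The end-to-end study that the tests and `scripts/acceptance.py`
run uses the same architecture at reduced widths so that the whole
pipeline — simulate 40 patients, train both networks, evaluate held-out
patients — completes on one CPU core in roughly ten minutes:

* localizer: fire ladder (4,8,8)×2 / (6,12,12)×3 / (8,16,16)×4, ASPP out
  24 channels, trained on every other slice for 8 epochs (batch 8);
* segmenter: depth 3, base 8 channels, trained for 20 epochs (batch 4) on
  96×96 ground-truth-guided crops (a box that bounds any phantom heart
  with the default margin) block-averaged 2× in-plane (48×48×10 inputs);
  at inference the predicted labels are restored by nearest-neighbour
  upsampling before paste-back;
* cohort: 40 patients (8 per class), 20 % held out at patient level
  before any training.

The segmenter's epoch count sits at the top of the short-schedule range
because its validation curve is still climbing through the first dozen
epochs at these widths; the localizer converges faster. The 2× in-plane reduction costs boundary precision (the
systolic myocardial wall is ~4 voxels at reduced resolution), which is
visible as lower ES scores.

## Numerical choices and conventions

* Coordinates are 0-based (row, column, slice), all ranges half-open;
  NIfTI affines are carried through untouched.
* Intensity normalization is a per-volume z-score (crop re-normalized
  after extraction); volume-level statistics avoid inter-slice seams.
  Constant volumes are rejected.
* Argmax ties resolve to the lowest class index (background first) in
  both networks — deterministic by construction.
* Batch normalisation uses batch statistics during training and running
  averages (momentum 0.1, ε = 1e-5) at evaluation.
* Attention resampling is bilinear/trilinear factor-2 interpolation with
  clamped edges (half-pixel sampling); the sigmoid keeps α strictly
  inside (0,1).
* The ASPP pooling branch is in-plane 2×2 max pooling restored by
  nearest-neighbour upsampling (edge-padded when the feature map is odd).
* The attention gate's intermediate width defaults to half the skip
  channels; the decoder's low-level feature is taken after the first
  pooling stage — both config-exposed, as the architecture leaves them
  open.
* Crop centering pads with the smaller share first (split ⌊·/2⌋ /
  ⌈·/2⌉); volumes pad with their minimum intensity, labels with
  background.
* He-normal weight initialisation, seeded per network from the
  configuration.

## Known limitations

* The engine is single-threaded except for BLAS and the im2col kernels;
  it is sized for phantom studies, not full-resolution clinical training.
* Only ED/ES frames are modelled; 4D cine NIfTI parsing is out of scope.
* Hausdorff/surface distances are not implemented (DSC and IoU only).
* The pathology geometry table is a documented stand-in: class labels
  drive geometry ranges, not physiology.
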