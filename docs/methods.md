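# Methods

## Problem and model

`conunet` segments lung tumors on CT slices with guidance from PET-like
intensity information that the network synthesizes itself.  The model is a
*connected dual U-Net*: the first U-Net maps a CT slice to a pseudo-PET
image; the second maps the CT slice — concatenated channel-wise with the
pseudo-PET — to a tumor-probability map.  Each decoder stage of the first
U-Net additionally feeds its feature map into the resolution-matched encoder
stage of the second U-Net (cross-network skip concatenation), so the learned
PET representation guides segmentation at every scale, not just at the
input.

Every convolution block is a 3x3 padded convolution followed by instance
normalization and a leaky ReLU (slope 0.01); two blocks form one stage.
Downsampling is 2x2 max pooling with stride 2; upsampling is a learnable
2x2 stride-2 transposed convolution (a nearest-neighbor + 3x3 convolution
variant sits behind `upsample_mode="nearest"` for ablation).  Channel width
doubles per resolution level.  The PET head is linear — it is trained
against intensity-normalized PET in [0, 1] and clamping it would bias the
regression; the segmentation head ends in a sigmoid.

At the reference configuration (base width 48, five resolution levels,
single-channel input) the dual network has 36.73M trainable scalars.  The
exact channel plan is not uniquely determined by the parameter budget alone;
width 48 with doubling was chosen as the smallest round plan consistent with
a ~36.6M budget, and `base_width` stays configurable (the test suite uses 8).

Two readings of the published block recipe were possible; we use the
conventional Conv -> InstanceNorm -> LeakyReLU ordering (the literal
"activation first" composition is available via `activation_first=True`).
A stride-1 2x2 pooling would not downsample at all, so pooling uses
stride 2, the standard U-Net choice.

## Training objective

Training uses two disjoint study pools:

* **Data A** — studies with CT and acquired PET, but no tumor masks;
* **Data B** — studies with CT and expert masks, but no PET.

The loss is `L = w*C + H + F`:

* `H` — mean squared error between the first U-Net's pseudo-PET and the
  acquired PET, on Data A;
* `F` — focal loss (gamma 2, probabilities clipped at 1e-7) plus soft Dice
  loss (smoothing 1e-6 in numerator and denominator), on Data B;
* `C` — consistency: MSE between the student's pseudo-PET on a Data B CT
  and a teacher network's pseudo-PET computed from a randomly quarter-turned
  view of the same CT, with the teacher output rotated back into the student
  frame before comparison.

The teacher is an exponential moving average of the student,
`theta'_t = alpha * theta'_{t-1} + (1 - alpha) * theta_t` with
`alpha = min(1 - 1/(step+1), 0.99)` where `step` counts optimizer
iterations; the teacher receives no gradient and is initialized as a copy of
the student.  The consistency weight ramps down as
`w = 0.1 * exp(-5 * (1 - T)^2)` with `T = clamp(1 - epoch/80, 0, 1)`; we
read the ramp variable as the epoch index (so the ramp spans 80 epochs) and
clamp `T` at zero so `w` settles at its floor rather than ramping back up.
Both interpretations — per-iteration vs per-epoch ramp, clamped vs free `T`
— were open; the choices are exposed as `ramp_length` and documented here.

The published index sets of the combined loss attach the PET term to the
mask-only pool and the segmentation term to the PET-only pool, which is
inconsistent with the data each pool actually carries; we follow the
training narrative instead (H on Data A; F and C on Data B).

Optimization is Adam at learning rate 1e-4 with cosine decay to 1e-5 over
the configured epochs, batch size 8 per pool; each step draws one batch
from A and one from B, cycling the smaller pool.  Joint geometric
augmentation (rotation, flipping, cropping applied identically to every
grid of a sample, nearest-neighbor for masks) is available through
`AugmentationSpec` and off by default in the desk-scale runs.  The
checkpoint with the
best validation Dice is kept; validation and test Dice are study-wise
(slices pooled per study before scoring), matching how per-study mean ± SD
results are normally aggregated.
The segmentation head's 1x1-convolution bias is initialized to -2 so the
initial foreground probability reflects a sparse-tumor prior (~0.1 rather
than 0.5); with a zero-initialized head the first epochs are spent
suppressing background and short training runs plateau far lower.

## Tumor-area detection

Refinement of a predicted mask volume runs in three stages:

1. **Rotation expansion.**  Every CT slice is followed by its 90/180/270
   degree rotations (4x sequence length); the model predicts a tumor
   segmentation image (TSI) for each entry.  Each TSI is mapped back to the
   original frame before any coordinate is extracted — without un-rotation
   the later clustering would mix four coordinate frames (a flag preserves
   the literal uncorrected reading via the provenance records).
2. **Quadruple clustering.**  The middle slice of the longest contiguous
   tumor-positive run anchors a window of up to 21 TSIs (10 on each side,
   clipped to the run).  On each selected TSI the two mutually farthest
   tumor pixels form a quadruple `(x_l, y_l, x_r, y_r)`; the diameter search
   runs on the convex hull with an exact integer-distance brute force as a
   degenerate-set fallback, and ties break to the lexicographically smallest
   pair so the pipeline is deterministic.  2-means clustering (10 restarts,
   300-iteration cap, fixed seed) splits the quadruples; a size tie breaks
   to the tighter cluster, then the lower label.
3. **Non-critical-area filtering.**  Column means of the majority cluster
   give two points; their bounding box padded by `lambda` pixels (default
   50, CLI-overridable) and clipped to the image becomes the rectangle mask
   `U`.  Every CT slice is multiplied by `U` (fill value 0, configurable)
   and re-predicted, and the refined mask is intersected with `U`, so no
   positive survives outside the detected region.

Multiple simultaneous tumors are out of scope: the longest-run rule embodies
a single-tumor assumption.

## Synthetic phantoms

The generator emulates the statistical structure the method assumes, not
anatomy: a bright body disc (intensity 0.45) with two dark elliptical lung
fields (0.12), one bright ellipsoidal tumor (lung + 0.75 contrast) coherent
across slices, Gaussian noise (sigma 0.03), and a PET channel that is a
Gaussian-blurred (sigma 2 px) tumor indicator at 5x background over a low
body background.  An optional distractor blob (probability 0.25) appears in
the opposite lung and never enters the mask — it emulates the transient
spurious detection the area detector exists to remove.  It is deliberately
*not* a tumor clone: its contrast is sub-tumor (0.45 vs 0.75, a
vessel/consolidation analog), it is no larger than the tumor, and its slice
range is disjoint from the tumor run — a tumor-identical blob labeled
background would make the 2-D slice labels contradictory and the task
unlearnable.  Defaults are
64x64 pixels and 48 slices with in-plane tumor radii of 4–9 px and an
axial semi-axis 1.5x the in-plane radius, so tumor runs are long enough to
exercise the 21-slice window.

The A/B split mirrors the study design: of the training studies, half keep
only (CT, PET) and half only (CT, mask); validation and test keep masks.
With 126 studies at fractions (0.8, 0.1, 0.1) the split is 100/13/13.

What phantom results do *not* show: robustness to real CT texture,
attenuation artifacts, irregular tumor margins, multi-focal disease, or
inter-observer label noise.  Passing the phantom recovery tests shows the
optimization and plumbing work end to end, not clinical performance.

## Metrics and preprocessing

Dice and IoU follow their set definitions, with the both-empty case defined
as 1 and the one-empty case as 0.  HD95 is the 95th percentile of the
pooled symmetric surface distances computed by Euclidean distance transform
(surfaces are mask-minus-erosion); when exactly one mask is empty the value
is undefined and the image diagonal in mm is reported with a per-study
flag, keeping aggregates finite.  Report SDs are population SDs.

Preprocessing resamples in-plane to 1 mm / 512x512 (linear for intensities,
nearest-neighbor for masks; slice axis untouched) and center-crops to
288x288, recording offsets so predictions map back to the 512 grid.
Evaluation defaults to the un-cropped grid.  Odd-sized inputs are rejected
by the network; the CLI pads symmetrically to the nearest valid size and
un-pads predictions.

## Numerical backend

The network, its gradients and Adam run on a compact reverse-mode
automatic-differentiation engine over numpy arrays (`conunet.nn`):
im2col+GEMM convolutions, 2x2 stride-2 transposed convolutions and max
pooling, instance normalization, and the elementwise/reduction primitives
the losses need.  Parameters are float32; every layer gradient is verified
against central finite differences in float64 in the test suite.  All
randomness flows through explicitly passed `numpy.random.Generator`s, so
training and refinement are bit-reproducible for a fixed seed.

## Problem sizes in the test suite

The suite trains a base-width-8 model for 20 epochs on 200 phantom slices
of 64x64 (about 260 optimizer steps) for the recovery and refinement
checks, and three-seed pairs of 8-epoch runs for the ablation-direction
check; these sizes were chosen as the smallest at which training reliably
separates tumor from background on phantoms.

## Known limitations

* Single tumor per study; the detector's longest-run and majority-cluster
  rules actively discard secondary foci.
* The parameter count (36.73M) brackets, but does not exactly reproduce,
  the published 36.605M — the residual 0.35% lies in unpublished details
  (normalization affine terms, head composition).
* 2-D slice-wise inference only; no 3-D convolutions.
* CPU-only backend: practical for phantom-scale studies and desk-scale
  experiments, not for full-resolution clinical training runs.
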