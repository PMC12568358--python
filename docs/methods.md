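# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Registration model

Given a moving volume `I_m` and a fixed volume `I_f` on the same `D×H×W`
grid (intensities in [0, 1]), the network predicts a dense displacement
field `u : grid → ℝ³` in **voxel units of the fixed grid**, and the warped
image is `I_w(i) = I_m(i + u(i))` (pull/backward convention).  Non-integer
sample positions are trilinearly interpolated; positions outside the volume
clamp to the nearest edge voxel.  Clamping (rather than zero-filling) was
chosen so that no artificial zeros enter the similarity loss at the
boundary; the gradient of the warp with respect to `u` is zero where a
coordinate is clamped.  The resampler exists twice by design — a
SciPy-based inference path (`udrnet.warp`) and a differentiable training
path (`udrnet._autodiff.grid_sample_trilinear`) — and the test suite pins
their agreement to ~1e-5.

### Architecture

Encoder level *i* (of `levels`): Conv3×3×3 → ReLU → Conv3×3×3 → ReLU, then
2× max pooling; the pre-pool features feed the matching decoder level via a
skip connection.  A bottleneck conv block sits at the coarsest resolution.
Decoder level *i*: transposed 3×3×3 convolution with stride 2 (doubling all
spatial dims; literal transposed convolution, not trilinear upsampling),
scHAF filtering of the skip features (or raw pass-through in the ablation
baseline), channel concatenation, then two Conv+ReLU layers.  A final 3×3×3
convolution with **zero-initialized weights** emits the 3-channel field, so
an untrained model is exactly the identity transform — the standard
stabilization for unsupervised registration, and the basis of the
"pre-registration baseline" reported by the results object.

Channel widths are free parameters.  Full-scale default: 4 levels, encoder (16, 32, 32, 32), decoder
(32, 32, 32, 16), 16-channel pre-head.  Desk-scale preset: 3 levels,
encoder (4, 8, 8), decoder (8, 8, 4), 8-channel pre-head — 39.5k parameters
with scHAF, 27.3k without.  Spatial dims must divide `2^levels` (one pool
per level; e.g. 3 levels map 32³ to a 4³ bottleneck).

### scHAF

For shallow features `F` with C channels: the *channel branch* applies a
learned 1×1×1 convolution collapsing C channels to a single spatial map,
gated by a sigmoid, broadcast over channels, and multiplied with `F`.  The
*space branch* global-max-pools and global-average-pools `F` to two
length-C vectors, concatenates them (2C), applies a two-layer MLP
2C → ⌈2C/ratio⌉ → C (ReLU between; ratio 2 by default, i.e. compress to C
then restore), gates with a sigmoid, broadcasts over space and multiplies
with `F`.  Fusion concatenates the elementwise product, sum and maximum of
the two branch outputs (3C channels) and maps back to C with a 3×3×3
convolution.

Two deliberate conventions: (1) the branch *names* are kept as scHAF
defines them even though they are transposed relative to common attention
terminology — the 1×1×1-conv spatial-map branch is called "channel" and the
pooled per-channel branch "space"; the constructions are what is
implemented and tested.  (2) The gating activation is a free
design choice; sigmoid is the default because it bounds attention
weights in (0, 1), and `attention_activation="none"` disables it.

### Losses and training protocol

Training minimizes a similarity loss alone: `1 − NCC` (default) or MSE,
averaged per pair over a batch.  NCC is computed globally over the whole
volume — the formula used has no local window, and the package does not
extrapolate to windowed NCC.  NCC is the default because alignment quality
is judged primarily by NCC; MSE is available by flag.  An optional
forward-difference smoothness penalty on the field (`lambda_smooth`,
default 0) is provided as a diagnostic regularizer but is off by default,
matching the similarity-only training strategy.

Reference protocol (dataclass defaults): Adam, learning rate 1e-5, up to
150 epochs, batch 16, random seed 666, early stopping when the test loss
fails to descend for 5 consecutive epochs.  "Descend" means strict
improvement on the best value seen so far; ties count as non-improvement.
The returned model carries the weights of the best test-loss epoch (a
config flag returns the last epoch instead).  With a 20/10 split there is
no third subset, so the held-out pairs double as the early-stopping signal;
this conflation of validation and test is methodologically weak but is the
protocol implemented here.

Desk-scale preset (`TrainConfig.desk_scale` / `NetworkConfig.desk_scale`):
32³ volumes, batch 2, Adam 1e-3, 30 epochs over 20 pairs = 300 gradient
steps.  The learning rate differs from the reference value because 300
steps from a zero-initialized head need a much larger step size to make
progress; the widths were sized for single-CPU wall-clock (a full recovery
run takes ~2.5 minutes).  These problem sizes are the package's documented
test configuration, distinct from the full-scale defaults.

## NumPy autodiff core

No deep-learning framework is used.  `udrnet._autodiff` implements
reverse-mode differentiation over float32 NumPy arrays for exactly the
operator set the model needs (convolution, transposed convolution, max
pooling, global pooling, trilinear grid sampling, elementwise algebra,
reductions); `udrnet._nn` adds layers with He-uniform initialization from
an explicit RNG and an Adam optimizer.  Convolutions run through numba
kernels whose loop nest keeps the K³·C input rows for one output row in L1
and vectorizes along the contiguous axis; the input gradient reuses the
forward kernel (it is a correlation with the flipped, channel-transposed
kernel).  Every custom backward pass is validated against central
differences in the test suite, and the forward convolution against
scipy.ndimage and a brute-force scatter oracle.

Numerical notes: `sqrt` backward guards the origin with a 1e-12 floor; NCC
adds 1e-8 under the square root of its denominator (the metric-path NCC has
no epsilon and raises on constant images instead); elementwise `maximum`
routes tie gradients to its first argument; the trilinear warp gradient is
undefined exactly at integer displacements (kink) and tests evaluate away
from them.  All randomness flows from explicit `numpy.random.Generator`
seeds; with a fixed seed, runs are bitwise reproducible on a given
platform/BLAS.

## Preprocessing

Windowing maps Hounsfield units through a width/level ramp: values at or
below `WL − WW/2` → 0, at or above `WL + WW/2` → 255, linear in between.
The default window is the conventional lung window (WL −600, WW 1500),
configurable everywhere.  Min-max normalization maps
each volume to [0, 1]; a constant volume normalizes to all zeros with a
warning rather than raising, so batch pipelines survive degenerate inputs.
Depth cropping removes slices from the start and end of the last axis,
split evenly, with an odd remainder taken from the end (e.g. 208 → 192
removes 8 + 8).

## Synthetic data

`make_phantom` builds a piecewise-smooth two-region image: a dark
soft-edged ellipsoid ("parenchyma", ~0.15) inside a brighter shell
("body", ~0.75), containing alternating Gaussian bumps (nodule-like) and
dilated line segments (vessel-like), Gaussian noise (sd 0.02), clipped to
[0, 1].  The mask is the ellipsoid.  `make_smooth_dvf` smooths
per-component white noise with a Gaussian (σ = 8 voxels) and rescales so
the peak displacement magnitude is exact.

A pair is constructed so the ground truth is *exactly* recoverable: the
phantom is the moving image, and the fixed image is the phantom pushed
through a generated field `g` with the package's own pull-convention warp
(`fixed = warp(moving, g)`, masks likewise).  Hence `warp(moving, true_dvf)`
reproduces the fixed image bitwise and a perfect model would output
`true_dvf` — this construction pins the warp-direction convention and gives
every downstream test a sharp target.

Deformation amplitude was calibrated once at the default 32³ scale and then
frozen: 6-voxel peak displacement with σ = 8 gives mean pre-registration
Dice ≈ 0.87 (the task is clearly non-trivial, below the 0.9 calibration
target) while every finite-difference Jacobian determinant stays positive
(min ≈ 0.5, fold-free).  The calibration scanned only pre-registration
overlap and Jacobians, never training outcomes.

What the phantoms do **not** emulate: real CT noise texture and artifacts,
anatomical variability between patients (each pair is one phantom deformed,
not two acquisitions), sliding motion at the pleura (the generated fields
are globally smooth, whereas breathing induces discontinuities along the
lung surface), and intensity changes between breathing phases (the
deformation is intensity-preserving by construction).  Passing the
synthetic-recovery test therefore shows that the architecture, warp,
losses and training loop *can* recover smooth deformations it is trained
to explain — it does not predict performance on clinical lung CT.  Full-scale
benchmarks (e.g. Learn2Reg lung CT, requiring GPU-scale training of 192³
volumes) are beyond desk scale and out of scope here.

## Known limitations

* Whole-volume batching only; 192³ at batch 16 is far beyond desk-scale
  memory, and no patch sampling is implemented.
* No diffeomorphic parameterization or inverse-field computation; large
  amplitudes can fold (the generator's defaults are calibrated fold-free).
* Displacements are in voxels and anisotropic spacing is not corrected
  inside the warp; physical-space (mm) fields are out of scope.
* The scHAF ablation at desk scale is a structural contrast (parameter
  counts, both variants train and evaluate); the sub-point metric deltas
  reported at full scale are below desk-scale resolvability, so no
  superiority claim is attached.
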