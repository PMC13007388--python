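# Methods

This note documents the model, the conventions the implementation fixes
where more than one reading was defensible, the synthetic data the
package is exercised on, and what the tests do and do not establish.

## Streamlines as tokens

A streamline is an ordered, orientation-free 3-D polyline in world RAS
millimeters. Preprocessing resamples each streamline to a fixed
`n_points = 15` by piecewise-linear interpolation at equal arc-length
increments along the source polyline (endpoints preserved exactly).
Linear interpolation is the field default; no spline smoothing is
applied. Note that arc-length resampling is exactly idempotent only for
curves with equal chord lengths (e.g. constant curvature); for smooth
streamline-like curves a second pass moves points by a vanishing amount,
and the tests pin the exact property on a helix.

Coordinates are normalized per axis into [-1, 1] by the affine min-max
map x' = 2 (x - min) / (max - min) - 1. Normalization statistics are
computed **per subtractogram** over the union of its streamlines'
points, not per whole tractogram: training re-normalizes after every
augmentation draw, so training-time statistics are inherently
per-subtractogram, and inference matches training. (Whether whole-
tractogram statistics at inference would behave differently is an open
sensitivity question; the partition-stability metric in
`fiberparc.infer.prediction_flip_rate` quantifies the per-subtractogram
variability that this convention induces.)

Tokenization flattens the 15 x 3 normalized coordinates to 45 values in
the first token entries and fills the remaining `d_model - 45` entries
with a learned *bias-free* linear map of those same 45 values. A full
learned projection to `d_model` is available via
`ModelConfig(token_mode="projection")` for sensitivity checks; the
padded reading is the default because it keeps the raw geometry visible
to the encoder verbatim. No positional encoding is added on either axis:
the context axis must remain permutation-equivariant, and the point axis
is already flattened into the token.

## Encoder and head

`n_layers = 8` encoder layers (full scale), each a single-head
self-attention sublayer and a 256-unit feed-forward sublayer, both with
residual connection, dropout (rate 0.1, train mode only) on the sublayer
output, and **post-norm** layer normalization (residual add, then
LayerNorm, eps 1e-5) — the original transformer-encoder arrangement,
chosen because the architecture is shallow enough not to need pre-norm
stabilization. The head is tokenwise (each streamline receives its own
logits, as the task demands): linear(d_model -> 256) -> ReLU ->
linear(256 -> n_classes), n_classes = 1600 clusters at full scale.

The network, backpropagation, and Adam are implemented in NumPy
(float32). Analytical gradients are verified against central finite
differences in float64 to ~1e-4 relative error (the key-projection bias
has an exactly zero gradient by softmax shift-invariance). Permutation
equivariance over the context axis holds to 1e-4 in float32, which is
the tolerance the tests use. Eval-mode forward passes are bit-
deterministic; stochasticity is confined to dropout and augmentation.

## Training conventions

- **Epoch = optimizer step.** With subtractograms sampled randomly from
  subjects there is no dataset-pass semantics, so the schedule length is
  the step count. Full-scale training used 10,000 steps of 64
  subtractograms at context 2000; desk-scale defaults are far smaller.
- Cosine annealing without restarts or warmup:
  lr(t) = lr0 (1 + cos(pi t / T)) / 2.
- Adam with L2-coupled weight decay 1e-3 (added to the gradient of
  weight matrices; biases and LayerNorm gains are not decayed).
  Decoupled (AdamW-style) decay would be a defensible alternative.
- Gradient clipping at global norm 1.0 as a divergence guard, disabled
  by `TrainConfig(grad_clip=None)`; a non-finite loss aborts with a
  diagnostic.
- Per-streamline cross-entropy on cluster ids, unweighted (inverse
  class-frequency weighting is available behind a flag but off by
  default, having shown no benefit).
- Checkpoint selection: macro-F1 on a fixed set of held-out
  subtractograms sampled once at startup without augmentation; the best
  validation checkpoint is returned.

## Augmentation

Applied to every subtractogram of every batch, then re-normalized to
[-1, 1]^3:

- **Rotation**: one rigid rotation per subtractogram (the context
  rotates as a whole), with per-axis angles drawn uniformly from
  +-45 deg (left-right axis) and +-10 deg (anterior-posterior,
  superior-inferior). Composition is extrinsic Rz Ry Rx (x first); with
  the small AP/SI ranges the order effect is minor, but the convention
  is fixed for reproducibility. The pivot is the origin of the
  normalized frame; re-normalization absorbs bounding-box changes.
- **Noise**: i.i.d. zero-mean Gaussian offsets, sigma = 0.001
  interpreted in normalized units, since it is applied between
  normalization and re-normalization.
- **Flip**: each streamline's point order reversed independently with
  p_flip = 0.5, promoting directional invariance of the orientation-free
  streamlines.
- **Hemisphere dropout**: with probability p_hemi = 0.3 a subtractogram
  is drawn from a single hemisphere. Hemisphere membership is the sign
  of the mean x coordinate in *world* (pre-normalization) space, where
  x = 0 is the anatomical midline; mean x >= 0 is "right". The side is a
  fair coin among the hemispheres actually populated in the subject, so
  the contract stays total for fully unilateral inputs.

## Inference

Whole-tractogram prediction resamples all streamlines, applies one
seeded random permutation, partitions contiguously into subtractograms
of `context_size` (default 2000), pads the final group by repeating its
own members (repetition keeps the group's normalization statistics
sane, and padded duplicates receive identical labels by equivariance,
so discarded padding is well-defined), normalizes each group jointly,
and batches groups (default 512 per forward pass) through the eval-mode
network; argmax cluster ids are returned in the input order and can be
mapped many-to-one onto tract ids via a `LabelMap`. No test-time flip
averaging or multi-context ensembling is performed.

## Synthetic phantoms

The generator produces what the method assumes of real tractograms, and
only that: smooth coherent bundles (cubic-spline centerlines through
control points; per-streamline rigid Gaussian lateral offsets clipped at
3.5 sigma so hemisphere membership is a construction guarantee; small
per-point jitter; random fractional end-truncation), mirrored across the
midline into distinct left/right classes, plus a configurable fraction
(default 10%) of incoherent outliers (random high-curvature 3-anchor
curves spanning the same volume, mimicking false-positive streamlines).
The default `bilateral6` phantom has three mirrored pairs of 1800
streamlines each (vertical projection-like, arched association-like,
dorsal anterior-posterior-like geometries) plus outliers, ~12,000
streamlines total; `hemispherotomy` adds an arching commissural bundle.
`ablate_hemisphere` removes streamlines on one side with probability
1 - keep_fraction and truncates midline-crossing streamlines at the
midline, leaving residual fragments — the post-hemispherotomy regime.

At the default scale the outlier class is not linearly separable from
the bundles in raw coordinates (verified by a LinearSVC check in the
tests), so label recovery genuinely requires a nonlinear/contextual
model. What the phantoms do **not** emulate: anatomical bundle shapes
and adjacency, realistic outlier statistics, partial-volume and
tracking-error correlations, scanner/protocol variability, or the
1600-cluster granularity of a population atlas. Passing the phantom
tests therefore demonstrates mechanism (the pipeline trains, the
augmentations confer the intended invariances, centering behaves as
claimed) — not clinical-grade accuracy on real data.

## Desk-scale problem sizes

The training-based checks use a reduced configuration chosen once:
token width 64 (the smallest that accommodates the 45 flattened
coordinates comfortably), 2 layers, 128-unit FFN and head, batches of
one subtractogram. Label recovery trains 2000 steps at context 512 and
is evaluated on an independently generated phantom (3 seeds); the
augmentation comparisons (flip vs. no flip, hemisphere dropout vs.
none) train 600 steps at context 256 and are directional means over 3
seeds. The sklearn-style estimator defaults mirror this desk scale;
full-scale values are the `ModelConfig`/`TrainConfig` defaults.

## Known limitations

- The NumPy engine is single-device CPU; there is no GPU path, and
  large contexts pay the quadratic attention cost without kernel
  fusion. Context 2000 costs roughly a second per subtractogram per
  forward pass on one core.
- TRK/TCK support covers points only; per-point scalars and per-
  streamline properties are out of scope, as are VTK polydata and
  compressed formats.
- The Wilcoxon machinery uses the exact null for n <= 25 without ties
  and the tie-corrected normal approximation otherwise; very small
  cohorts with heavy ties fall back to the approximation.
- Hemisphere dropout assumes the subject's anatomical midline is at
  x = 0 in world coordinates; tractograms in arbitrary scanner frames
  should be centered (`center_to_atlas`) first.
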