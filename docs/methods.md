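# Methods

## Problem and data model

The package segments two structures from a 3D CT-angiography-like intensity
volume — the aortic root (label 1) and the coronary arteries (label 2),
against background (label 0) — and then decides from the segmented geometry
alone whether the coronary origins are normal or anomalous (AAOCA). Volumes
are handled in a canonical `(i, j, k)` axis order with `k` running
inferior → superior, so `data[:, :, k]` is the k-th axial slice; NIfTI inputs
are reoriented to the closest RAS-canonical form on load. This convention is
ours (source orientation handling is otherwise ambiguous), and everything
downstream that mentions "Z" or "axial" relies on it.

## Preprocessing

Two steps, in this order:

1. **Resize** to a fixed cubic grid — 320³ voxels at clinical scale, 64³ as
   the desk-scale default used throughout the synthetic experiments.
   Trilinear interpolation for intensities, nearest-neighbour for label maps
   (resampling can then never invent a label value). Sampling is
   corner-aligned, so constants and ramp endpoints are preserved exactly;
   spacing is rescaled per axis, and anisotropic inputs are stretched to the
   cube without aspect-ratio preservation, as a fixed-dimension resize
   implies.
2. **HU window** centred at 100 HU, width 700 HU, i.e. [−250, 450]; values
   outside are saturated to the bounds (idempotent by construction).

Before entering a network, the windowed volume is mapped affinely to [0, 1]
(`to_unit_range`). Some fixed normalisation is needed for stable training;
the affine map of the window is the least surprising choice.

## Single-plane attention U-Net

One identical 2D network per orthogonal plane. The architecture is an
encoder–decoder with attention-gated skips:

- `depth` encoder blocks (two 3×3 conv + ReLU each) at `base · 2^i` channels,
  each followed by 2×2 max pooling; a bottleneck block at `base · 2^depth`.
- Decoder stages mirror the encoder: 2× nearest-neighbour upsampling + 3×3
  conv, an **additive attention gate** on the skip
  (`ψ = σ(w·relu(W_x s + W_g g))`, one-channel mask multiplying the skip),
  concatenation, then a conv block.
- A 1×1 convolution emits three channels through an element-wise **sigmoid**.

"Multi-class with binary cross-entropy" is read as three independent binary
problems — per-channel sigmoid with BCE averaged over channels — rather than
softmax cross-entropy. This matches the downstream use: each class map is
thresholded independently, so the maps need not sum to one.

Architecture depth/width are not part of the clinical protocol; the defaults
(`depth=4`, `base_filters=16`, ≈ 2.2 M parameters) are exposed in config, and
the desk-scale experiments use `depth=3`, `base_filters=8` (≈ 136 k
parameters), which is ample for phantom anatomy. Input sides must be
divisible by `2^depth`.

The engine underneath (im2col convolutions on BLAS, pooling, attention
gates, Adam, hand-written backpropagation) is implemented in `coroseg.nn`
and verified against central finite differences in float64.

### Training

- Adam, learning rate 1e-4 (clinical reference default; the desk-scale
  experiments use 1e-3, which converges within their few epochs on the
  much easier phantom statistics).
- Mini-batches of 10 slices drawn uniformly at random from the training
  pool; slices without foreground stay in the pool.
- Early stopping on validation loss with patience 15 (the monitored
  quantity had to be chosen; validation loss is the obvious one); the
  best-validation parameters are returned. An "epoch" is `steps_per_epoch`
  mini-batches (default: one pass-equivalent over the pool).
- Augmentation per sampled slice: one rotation from ±7°, one shift from
  ±22 px in width and ±22 px (axial) / ±72 px (sagittal, coronal) in
  height, one zoom from 0.85–1.15, composed as a single affine and applied
  identically to image (bilinear) and labels (nearest). Out-of-frame pixels
  take the image minimum (the window floor) and label 0. The pixel ranges
  are defined at the 320-px clinical slice side; `AugmentConfig.scaled`
  shrinks them proportionally for smaller grids (64/320 in the desk-scale
  runs). Validation is never augmented at threshold-calibration time.

## Multi-view integration and fusion

Each plane model is run slice-by-slice along its axis and the 2D outputs are
restacked into 3D per-class probability volumes; the three views are
combined by the voxel-wise arithmetic mean. Binarization thresholds are
fitted per class on validation pairs as the value on a 0.01-resolution grid
(matching the two significant digits of the clinically fitted 0.30/0.15
reference values, which ship as config defaults) that maximises the **mean
per-volume Dice**, with ties resolved toward the smaller threshold. Fusion:
neither class above threshold → background; one above → that class; both
above → the larger probability, with exact ties going to the aortic root
(lower class index — undocumented upstream, measure-zero, fixed for
determinism). The background channel is ignored: background is defined by
exclusion.

## Geometry classifier

1. Optional **minimum-size filter**: coronary components smaller than
   `min_component_ml` are dropped (default 0 = off). This guards against
   spurious disconnected blobs of mislabelled voxels inflating the component
   count; removals are recorded as warnings, and removing everything is an
   error.
2. **Connectivity rule** on the label-2 mask only (the aorta is excluded),
   default 26-connectivity — thin oblique vessels fragment under
   6-connectivity; the neighbourhood is configurable. Counts of 1 or 3 are
   anomalous by anatomy; counts ≥ 4 are undefined in the clinical taxonomy
   and are classified anomalous with a warning (never normal — the
   recall-protecting direction); 0 after filtering is an error.
3. **Ostium detection** (two components only): per trunk, the coronary voxel
   minimising the Euclidean distance (scaled by spacing, via an exact
   distance transform) to any aorta voxel; "distance to the aortic wall" and
   "distance to the nearest aorta voxel" agree to within a voxel for thin
   structures. Ties break to the smallest linear (ravel-order) index.
4. **Origin angle**: `z_half` is the mean of the two ostium Z indices; the
   aortic centroid is the mean (i, j) of label-1 voxels on the nearest
   integer slice (exact .5 rounds to the lower index; if that slice holds no
   aorta the two adjacent slices are tried, then it is an error). Ostia are
   projected by dropping Z, and α is the 2D angle between the two
   centroid→ostium vectors (zero-length vectors are an error). The angle is
   deliberately computed in the axial plane only, as the projection
   construction implies.
5. **Decision stump**: α < θ ⇒ anomalous, with boundary equality reading as
   normal (documented, arbitrary). Fitting maximises training accuracy over
   midpoints of consecutive sorted angles; among equally accurate splits the
   midpoint of the widest separating gap wins (the maximum-margin choice).
   Non-separable training data yields the best achievable split plus a
   warning. The clinical reference threshold 73° is the shipped default; it
   is a reference, not a reproduction target, since the exact fitting set
   and split criterion used upstream are unknown.

The detected-ostium tie-break makes α exactly invariant under 90° in-plane
rotations only when each trunk's nearest-to-aorta voxel is unique; with
multi-voxel tie sets the picked voxel can shift by a voxel or two, which on
a 64³ grid moves α by a few degrees. The recovery experiments budget for
this (±8°).

## Phantom generator

Each phantom is a vertical aortic cylinder (default radius 10 voxels on a
64³ grid) plus 1–3 coronary tubes (default radius 2) that leave the aortic
surface at controlled azimuths and heights and curve outward and inferiorly
along quadratic Bézier paths rasterised as swept spheres. Variants encode
the classifier's taxonomy: `normal` (ostium separation drawn from the
121–154° normal quartile range), `anomalous_close` (20–46°, the anomalous
quartile range), `anomalous_shared` (one ostium, one component),
`anomalous_three` (three trunks), and a `retroaortic` flag variant whose
second tube wraps behind the aorta (kept outside the recovery experiments,
mirroring the known weakness of the approach on that subtype).

Geometric choices worth recording:

- **Ostial funnel**: at each true ostium the aorta carries a one-voxel-wide
  radial stalk from the wall to the tube's inner surface, and the tube
  starts just clear of the main wall (its first sphere tangent to it). This
  models the ostial junction and, importantly, makes nearest-voxel ostium
  detection well-posed on a discrete grid: without it, the flat facets of a
  discretised cylinder produce equidistant contact patches several voxels
  wide, and the tie-break can displace the detected ostium by ~10° of
  azimuth at radius 10.
- **Trunk Z offsets** default to 2–6 voxels so the halfway-plane projection
  is exercised non-trivially; for `anomalous_close` the offset is drawn from
  5–6 voxels, which guarantees the two tubes never touch even at 20°
  azimuthal separation (at radius 10 a 20° chord is ~3.5 voxels — less than
  two tube diameters).
- Intensities are class-conditional Gaussians on the HU scale (lumen
  N(350, 20), soft tissue N(−50, 20) — inside the window of interest, ~20
  noise SDs of contrast), with a σ = 0.5 voxel Gaussian blur applied to the
  noiseless field first to mimic partial-volume averaging.
- Everything derives from one `noise_seed`; datasets derive per-phantom
  seeds deterministically from a base seed and record them in a manifest.

What the phantoms do **not** emulate: cardiac motion, myocardium, valves,
calcifications, intramural tracts, real CTA texture, scanner artefacts, or
anatomical variability beyond ostium placement. Passing the synthetic
experiments therefore demonstrates that the pipeline's machinery (training,
integration, calibration, geometry rules) is correct — not that clinical
accuracy would match the reference results on real CTA.

## Desk-scale experiment sizes

The learning check trains the three plane models on 30 phantoms (plus 5
validation, 5 held-out test) at 64³ with depth 3 / 8 base filters, learning
rate 1e-3, 8 epochs of 40 mini-batches of 10 slices — about ten minutes on
one CPU — and asserts mean test Dice ≥ 0.85 (aortic root) and ≥ 0.60
(coronary) after calibration and fusion. These floors are sanity bounds for
phantom anatomy, far below what the pipeline achieves there (typically ~0.99
and ~0.9), and are not comparable with clinical-scale Dice. The
classification experiment fits the stump on 40 training phantoms and
classifies 40 disjoint test phantoms from ground-truth labels; with the
variant mix 50% normal / 20% close / 15% shared / 15% three-trunk the fitted
threshold lands in the 46–121° gap and the test metrics are exact
(accuracy = precision = recall = 1), mirroring the reference behaviour on
clinical test data.

## Known limitations

- The attention-gate variant and channel widths of the original clinical
  model are unspecified; ours is the standard additive gate with
  `c_int = channels/2`.
- Threshold calibration and stump fitting see only synthetic data here;
  the clinical reference values (0.30/0.15, 73°) are shipped as defaults
  but cannot be validated without clinical volumes.
- Nearest-voxel ostium detection is quantization-limited (see above);
  sub-voxel ostium localisation is out of scope.
- The retroaortic variant is generated but excluded from recovery claims;
  its tube's closest approach to the aorta is not necessarily its ostium,
  so angle-based classification is unreliable for it by construction.
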