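# Methods

This note documents the model, the numerical conventions, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not exercise.

## Coordinate and angle conventions

One convention is used everywhere (generator, moments, network, spatial
transform): `x` is the column index, `y` the row index, the origin is
the centre of the top-left pixel, and angles are measured from the +x
axis toward +y (the row direction). Because row 0 is drawn at the top,
a positive angle appears clockwise on screen. The image centre is at
`((W−1)/2, (H−1)/2)`; pose-code positions are offsets from it in
pixels. Rotating a point by φ maps `(x, y)` to
`(x cos φ − y sin φ, x sin φ + y cos φ)`.

## Image moments

Raw moments are `M_pq = Σ x^p y^q I(x, y)`. The centroid is
`(x̄, ȳ) = (M10/M00, M01/M00)`; the orientation from the second central
moments is `ᾱ = ½·atan2(2 μ11, μ20 − μ02)`, reduced to `[−π/2, π/2)`.
Two consequences shape everything downstream:

- **π ambiguity.** Second moments cannot distinguish a silhouette from
  its 180° rotation, so ᾱ is an *axial* quantity. Every angular
  comparison in the package uses the π-periodic distance
  `min_k |Δ + kπ|`, and angular agreement is measured with the pairwise
  Fisher–Lee T-linear association on doubled angles. (The mean-centred
  variant of that statistic is avoided deliberately: for near-uniform
  angle distributions the circular mean direction is arbitrary and the
  mean-centred estimator returns noise.)
- **Isotropy.** When `μ11 ≈ 0` and `μ20 ≈ μ02` the orientation is
  undefined; it is set to 0 by convention, and — important for training
  — such frames are flagged so the moment loss skips their angle term.
  The flag uses the second-moment eigenvalue ratio λ₁/λ₂ with threshold
  1.2: a circle's ratio is ≈ 1 up to antialiasing noise, while the
  benchmark's triangle (≈ 2.4) and rectangle (≈ 4.0) clear it by a wide
  margin. Without this skip, one third of XYRCS frames would pull the
  orientation head toward antialiasing noise.

Multichannel images are reduced to the channel mean before moments.  No
background thresholding is applied by default (thresholds move
centroids); a percentile-subtraction option exists for noisy stacks.
COM features (`com_x, com_y, com_angle, com_mag`) are the centroid
relative to the frame centre in Cartesian and polar form, the standard
descriptors for centred diffraction patterns; in that protocol the
angle guidance comes from `com_angle` and translation learning is
switched off (`learn_xy=False`).

## The network

**Equivariant trunk.** The lifting layer correlates the input with
`n_orient` rotated copies of each base kernel (rotation by bilinear
resampling about the kernel centre, precomputed as a `k²×k²` matrix per
angle; at multiples of 90° the matrix is an exact permutation). Group
layers then convolve over space *and* the orientation axis, with the
kernel for output orientation `r` spatially rotated by the r-th group
angle and cyclically shifted along its input-orientation axis.
Downsampling uses 2×2 average pooling, which commutes exactly with 90°
rotations on even grids (strided convolution does not — its sampling
grid is not closed under rotation — which is why pooling was chosen).
With zero `same` padding on square frames the rotate-by-90° ⇒
(spatial rotation + orientation shift) identity holds everywhere to
float32 round-off, not only on interior pixels.

**Heads.** `B_equi` flattens the final oriented feature map and applies
a two-layer MLP producing `(u_x, u_y, a, b)`; positions are
`(W/2)·tanh(u)` (bounded to the frame) and the angle is
`θ̂ = ½·atan2(b, a)`, i.e. the 2-vector `(a, b)` lives on the *doubled*
angle so θ̂ is axial in `[0, π)`. This is a deliberate deviation from a
full-circle `atan2` head: with π-periodic moment targets a full-circle
head receives two admissible pull directions per sample, and at the
desk-scale budgets used here its angle map reproducibly collapses over
a sector of the circle (measured circular correlation 0.2–0.6 versus
truth); the axial head has a single target direction per sample and
reaches angular RMS ≈ 0.08 rad under the same budget. A full-circle
mode remains available (`ModelConfig(angle_mode="full")`) for regimes
with long post-decay training, where the reconstruction loss can
resolve the full orientation.  `B_inv` max-pools over the orientation
axis (exactly invariant to cyclic orientation permutations) and applies
its own MLP to give `z_inv ∈ R^d`.

**Euler encoding.** `z_inv` is mapped to the unit sphere in `R^(d+1)`
by the hyperspherical construction
`E(z) = (cos z₁, sin z₁ cos z₂, …, sin z₁⋯sin z_d)` — successive planar
rotations applied to a fixed axis. `‖E(z)‖ = 1` everywhere and the
tangent directions `∂E/∂z_i` are mutually orthogonal at every point, so
latent directions act orthogonally on the decoder input.

**Decoder and spatial transform.** A conventional stack (linear →
nearest-neighbour ×2 upsampling + 3×3 convolutions, sigmoid output)
decodes `E(z_inv)` to the aligned image. The same-view reconstruction
applies the pose: rotate about the image centre by θ̂, then translate by
`(x̂, ŷ)`, with bilinear resampling and zero fill. The transform order
(rotate, then translate) makes the inverse mapping unambiguous: the
canonical object sits at the centre, and the decoder output is placed
into the input frame.

**Ablation model.** `equivariant=False` replaces the trunk with plain
convolutions at width `C·√n_orient`, which matches both the parameter
count and the FLOPs of the group trunk (group layer: `N·C_out·C_in·k²`
parameters; plain layer at width factor `a`: `a²·C_out·C_in·k²`).
Pooling, heads, decoder, and all training settings are unchanged.

## Training

The objective per step is `L_r + β(t)·L_m`. `L_r` is pixelwise MSE by
default (binary cross-entropy available for silhouette data). `L_m`
sums squared pixel errors on the positions (skipped when
`learn_xy=False`) and the squared π-periodic angular distance; frames
with degenerate moments contribute nothing, frames that are merely
isotropic contribute only their position terms. `β(t)` decays linearly
from β₀ = 10 to exactly 0 at half of the total step count and stays 0
(a cosine shape is available). Optimization is Adam at a fixed 1e-3
with global gradient-norm clipping at 5; the default batch size is 32 —
at this fixed learning rate the additional update steps per epoch are
what let the angle head converge within a ten-epoch budget. Moments of
the training stack are computed once and cached. A fixed seed makes
runs bit-reproducible on one device.

All tensors are float32 on a small reverse-mode autodiff engine
(`codae.autograd`) whose operations (convolution via im2col and BLAS
matmuls, pooling, bilinear grid sampling with gradients to both image
and coordinates, trigonometry) are finite-difference-checked in the
test suite.

## Synthetic benchmark

`generate_xyrcs` renders one shape per frame — circle, isosceles
triangle, or rectangle — with independently sampled factors: position
offsets uniform in ±image_size/6, orientation uniform in `[0, 2π)`,
brightness uniform in `[0.4, 1.0]`; shape bounding radius defaults to
image_size/4 and the position range is validated so objects never leave
the frame (otherwise moments and alignment are ill-defined). Rendering
is analytic-membership supersampling (4× per axis, box down-sampling),
which makes moment centroids sub-pixel accurate; every canonical shape
has its silhouette centroid at its own origin, so the recorded (x, y)
equals the rendered moment centroid to within antialiasing error
(< 0.5 px, asserted in tests). The triangle is isosceles — vertices
`(r, 0), (−r/2, ±0.55r)` — because an equilateral triangle has three-
fold symmetry and hence no defined second-moment orientation, which
would make the orientation factor unrecoverable. Canonical poses fix
the orientation factor's meaning: triangle apex and rectangle long axis
along +x at orientation 0. `generate_dsprites_like` provides
square/ellipse/heart silhouettes with a scale factor instead of
brightness. Factors are sampled continuously; metric computations bin
them (below).

What the benchmark does *not* emulate: noise (frames are clean
silhouettes), multiple or overlapping objects, non-uniform backgrounds,
and out-of-plane pose. Passing tests therefore demonstrate the
mechanics of pose disentanglement, not robustness on experimental data.

## Disentanglement metrics

All eight scores are normalized to [0, 1], 1 optimal. Continuous
factors and latents are discretized into 10 equal-count bins for the
intervention- and information-based metrics; predictor-based metrics
see continuous values. The orientation factor is binned modulo π and,
where a real-valued target is needed, represented as
`(cos 2θ, sin 2θ)` with the two sub-target scores averaged — both
choices honour the π ambiguity and avoid spurious wraparound penalties.

- `z_diff`: logistic-regression accuracy at identifying which factor
  was held fixed from mean absolute latent differences of matched
  pairs (chance level is 1/#factors).
- `z_var`: majority-vote accuracy of "the least-variable normalized
  dimension under a fixed factor"; collapsed dimensions are excluded.
- `irs`: per-dimension interventional robustness — one minus the
  normalized 0.99-quantile deviation of a dimension when its
  best-matching factor is fixed and the others vary, variance-weighted
  across dimensions.
- `dci`: the disentanglement component of the importance matrix
  (random-forest importances by default, lasso mode available):
  one minus the per-dimension entropy of its normalized importance
  row, weighted by relative importance.
- `sap`: per factor, the gap between the best and second-best
  single-dimension prediction scores. Scores are chance-corrected
  single-feature decision-tree accuracies, `(acc − chance)/(1 −
  chance)`, on the binned factors, with tree depth scaled to the level
  count. (Raw accuracies cannot reach the perfect-code limit because
  the runner-up dimension scores chance; linear R² mishandles the
  periodic factor.)
- `mig`: per factor, the normalized gap between the two largest mutual
  informations `I(z_j; f_k)/H(f_k)`, averaged.
- `jemmig`: per factor, `1 − (H(z*, f) − I₁ + I₂)/(H(f) + log B)` with
  `z*` the best dimension and `B` the latent bin count.
- `dcimig`: per-dimension MI gaps attributed to each dimension's top
  factor, the best gap per factor summed and normalized by `Σ H(f_k)`.

On a reference toy grid a one-to-one latent copy of the factors scores
≥ 0.95 on every metric and independent random latents score ≤ 0.1 on
the gap-style metrics (mig, sap, dci); the classifier-style metrics
(z_diff, z_var) have chance-level null baselines of 1/#factors by
construction, and irs's null baseline is likewise well above zero —
these are properties of the published constructions, not of this
implementation.

Reports are computed under two protocols: over all factors, or with the
pose factors (x, y, orientation) and their latent dimensions excluded —
the pose dimensions are taken from the model's own `z_equi` columns
when known, otherwise from a correlation-based assignment (|Pearson r|
for linear factors, Mardia circular–linear correlation on doubled
angles for orientation, correlation ratio for categorical factors;
threshold 0.5, below which a dimension stays "unnamed"; greedy
assignment, ties toward the lower dimension index). A best-of-seeds
selection utility (`select_best_run`, CLI `codae report`) implements
the multi-seed reporting rule as a post-hoc step over run outputs, not
inside any metric.

## Desk-scale study conditions

The end-to-end checks (test suite and `scripts/acceptance.py`) use
n = 2000 frames at 32×32 px, d = 2 invariant dimensions, 10 epochs,
fixed seeds — sizes chosen so the whole protocol (three training runs
plus metrics) completes in minutes on one CPU while still recovering
the pose factors cleanly (position correlation > 0.99, axial
orientation correlation > 0.9 on anisotropic shapes). Under these
conditions replacing the equivariant trunk with the parameter-matched
plain-convolution trunk lowers the eight-metric average by roughly
5 %, and disabling the moment guidance (β₀ = 0) lowers it by roughly
35 % — both ablation directions are robust across seeds; the
magnitudes at this scale are indicative, not definitive.

## Known limitations

- Orientation is learned modulo π by default; applications that need
  the full circle (polar asymmetric objects) should use
  `angle_mode="full"` with substantially longer post-decay training.
- The invariant branch is only exactly rotation-invariant at the group
  angles (360°/n_orient); intermediate rotations incur an
  interpolation-bounded error that shrinks as `n_orient` grows
  (default 8).
- Equivariance holds for rotations about the image centre; objects near
  the frame edge lose pixels under the spatial transform (zero fill).
- The MRC reader/writer covers the common single-particle subset
  (modes 0/1/2/6 read, float32 mode 2 write, no extended headers).
- No scale or reflection equivariance; depth/scale factors are out of
  scope.
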