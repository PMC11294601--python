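# Methods

This note documents the models, parameters and numerical choices behind
`cyclecell`, and what the synthetic benchmarks do and do not demonstrate.

## The dual-task cycle-GAN

Two cycle-GAN tasks share a common target domain B of clean binary membrane
images and are coupled only through their loss functions (soft parameter
sharing): task 1 translates raw grayscale images (domain A), task 2
translates membrane-enhanced images (domain C). Each task has a forward
generator into B, a reverse generator out of B, and one discriminator per
direction — eight networks.

Losses, per task, for the binary-producing generator:

* adversarial — mean squared error of the discriminator's s×s score grid
  against the "real" label 1 (least-squares GAN);
* identity — mean absolute error between G(b) and a real binary image b,
  discouraging the generator from altering images already in its target
  domain;
* cycle consistency — MAE between the round-trip reconstruction G(G′(b))
  and b, making the translation reversible.

Weighted total per task: `adv + λ_id·id + λ_cyc·cyc` with λ_cyc = 10 (the
cycle term carries ten times the adversarial weight) and λ_id = 5. λ_id is
not pinned by any published value; half the cycle weight is the customary
ratio in cycle-GAN practice and is configurable.

**Coupling.** The shared objective is `max(total_1, total_2)`. We take the
subgradient of the max: on each step only the arg-max (currently worse)
task's binary generator is updated, which in practice synchronises the two
tasks — neither can run ahead while the other lags. The reverse generators
and all four discriminators always train on their own losses.

**Discriminator labels.** The least-squares discriminator loss is
`½·MSE(D(fake), 0) + ½·MSE(D(real), 1)` (convention `standard`). An
alternative convention `as_printed` with the labels exchanged is selectable;
it duplicates the generator objective and is provided for comparison only.

**Optimiser and initialisation.** Adam with learning rate 0.002. The
first-moment decay β₁ defaults to 0.5 (the usual GAN setting); β₁ = 1, which
freezes the gradient moving average, is selectable for completeness (the
bias-correction term is skipped in that degenerate case). Weights are
Glorot-normal. Two modes exist: `per_layer` (std = √(2/(fan_in+fan_out)),
the standard scheme, default) and `paper_global`, a truncated normal bounded
by ±√(6/(nᵢ+nₒ)) where nᵢ = 862 and nₒ = 400 are *dataset* sizes (input and
output image counts) rather than layer fan counts — an unconventional
reading that is kept available rather than silently corrected; the std is
√(2/(nᵢ+nₒ)) so the bound sits at √3 standard deviations.

**Architecture.** Generators: 7×7 input convolution → two stride-2
downsampling convolutions → n residual blocks → two nearest-neighbour
upsample+convolution stages → 7×7 output convolution with tanh; instance
normalisation throughout. Discriminators: four stride-2 convolutions ending
in a 1-channel s×s score grid (PatchGAN-style, n_t = s² scores). Images are
mapped to [−1, 1] inside the model and the tanh output back to [0, 1].
Channel widths and residual depth are configurable; the published-scale
recipe (256×256, 6 residual blocks) is supported, while the default desk
recipe uses 64×64 images, 8 base channels and 2 residual blocks so a
200-epoch run completes in a few minutes on one CPU core. The networks are
implemented in a small NumPy layer stack with explicit forward/backward
passes (`cyclecell.nn`); convolution uses a shift-and-add scheme (one small
matmul per kernel offset), and gradients are validated against finite
differences in the test suite.

**Training loop.** Per step: sample a batch from each pool; update the four
discriminators; update the reverse generators on their task losses; update
the arg-max task's binary generator on the shared loss. Checkpoints are
taken every `checkpoint_interval` epochs (default 400, matching the
published cadence; the desk recipe uses 50–100) and the best checkpoint is
chosen by median held-out F1, ties resolved toward the later epoch.
Epoch-0 losses are recorded before any update on a fixed probe batch, so a
fixed seed reproduces them bit-for-bit. A NaN in the shared loss aborts
training, returning the checkpoints taken so far.

## The synthetic tissue simulator

The simulator supplies both the prior domain B and ground-truthed test
images; it emulates en-face RCM of the living epidermis.

* **Tissue mask** — islands bounded by closed composite quadratic Bezier
  curves through 6–12 jittered control points on a circle; islands are drawn
  sequentially, redrawn if they come within 2 px of an existing island, and
  may be clipped by a 3 px background frame so grooves always reach the
  border. `smoothness` (default 0.7) sets the control-point jitter.
* **Cell centers** — a hard-core (sequential inhibition) process: uniform
  candidates inside the tissue (3 px clear of the contour) are accepted iff
  at least `min_distance` (default 10 px ≈ one keratinocyte diameter at
  1 µm/px) from all accepted points, until `round(density × tissue area)`
  points are placed or the proposal budget is exhausted (the result is then
  flagged saturated, not an error).
* **Membranes** — nearest-seed (Voronoi) affiliation of tissue pixels;
  pixels whose 4-neighbourhood spans two affiliations, plus the island
  contour, dilated to `membrane_width` (default 3 px). Rasterisation
  slivers (1–2 px crescents pinched off at the rim) are absorbed into the
  membrane so the invariant *one enclosed region per seed* holds exactly.
* **Rendering** — `clip(base × illumination × (1 + speckle) + blobs, 0, 1)`
  with base = `membrane_contrast` (default 0.75) on membrane pixels;
  multiplicative speckle is white Gaussian noise smoothed at 2 px and scaled
  to σ = 0.35; bright Gaussian blobs (organelle-like noise) appear at
  2×10⁻⁴ px⁻² with intensity 0.5; a low-frequency illumination field
  (smoothed at 64 px, amplitude 0.3) models brightness heterogeneity. With
  all noise at zero and contrast 1 the rendering equals the binary image
  exactly. The noise parameterisation is this package's own; published
  sources describe the degradations qualitatively (spatially correlated
  noise, bright organelle blobs, heterogeneity) and the defaults were chosen
  once to reproduce that appearance.
* **Default recipe** — 400 samples at 256×256 with density 0.0045 and two
  islands covering ~20–30% of the patch, giving roughly 70–110 cells per
  patch; all counts configurable.
* **Non-confluent variant** — disk cells placed by rejection sampling with
  the pairwise overlap bounded by `max_overlap_fraction` of the smaller
  disk's area (closed-form lens area); `binary` holds disk outlines. This is
  the prior used for non-confluent cell cultures, paired with Canny rather
  than Gabor enhancement.
* **Reproducibility** — every generator is a pure function of its arguments;
  per-sample streams derive from `SeedSequence([seed, index])`, so sample i
  is reproducible in isolation.

What the simulator does *not* model: physically accurate confocal speckle,
3D sectioning, depth-dependent signal loss, real organelle morphology, or
membrane brightness variation along a cell boundary. Passing synthetic
benchmarks therefore demonstrates the machinery (losses, coupling, recovery,
scoring) under controlled conditions, not clinical performance on real RCM.

## Preprocessing

* **ROI** — stage 1 separates tissue from dark grooves with a morphological
  geodesic active contour on the inverse-Gaussian-gradient of the smoothed
  image, initialised from an Otsu blob, then eroded by 2 px to undo the
  smoothing bleed. Stage 2 tiles the tissue into 31 px windows and computes
  four GLCM features (homogeneity, contrast, dissimilarity, energy; 32 grey
  levels, distance 1, four angles). A supplied classifier may veto windows;
  without one, a 2-means split is used and the cluster with lower
  energy+homogeneity (noise-dominated texture) is vetoed — but only when the
  cluster centres are ≥ 1 standardised unit apart *and* the vetoed cluster
  is a strict minority, so uniform-texture images are never carved up. The
  active-contour and clustering stages are global, so the ROI is local only
  to ~99.5% under single-pixel perturbations.
* **Local normalisation** — (x − μ_w)/(σ_w + ε) over a 31 px window, then a
  symmetric rescale about 0.5 by the maximum |z|; invariant to global affine
  intensity changes, constant images map to 0.5.
* **Membrane enhancement** — maximum real Gabor response over a bank
  (orientations kπ/8, wavelengths 8 and 16 px; envelope elongated along the
  stripe so tubes outrank isotropic blobs), min-max rescaled; or a Canny
  edge map dilated by 1 px for the non-confluent variant.
* **Adaptive binarisation** — histogram equalisation (stretched back to
  [0, 1]) followed by a Gaussian-weighted local mean threshold; a pixel is
  foreground when it exceeds the local mean plus the offset, so constant
  images are all background.
* **Patching** — a frame is split into the largest grid of non-overlapping
  256×256 patches with offsets spread evenly from 0 to size−256 (a
  1000×1000 frame gives offsets {0, 372, 744}: nine patches covering all
  four borders and corners). Stitching averages overlaps and flags
  uncovered pixels. Full-image inference uses overlapping tiles at stride
  half a patch with averaged probability maps.

## Post-processing

* **Contour closure** — per island (foreground clustered by dilation at half
  `min_alpha`), the alpha complex of the membrane pixel cloud is taken from
  the Delaunay triangulation by keeping simplices with circumradius ≤ α.
  α is chosen per island as the smallest candidate making the complex
  connected and covering every point, floored at `min_alpha` = 12 px. The
  floor is the substantive choice: the smallest "single polygon" α for a
  broken ring is still the leaky open shape, so gaps below the cell-diameter
  scale must be bridged by fiat — 12 px ≈ one cell diameter means any
  membrane gap smaller than a cell is treated as an artifact. The complex
  boundary is drawn onto the input (union), so foreground is never removed.
* **Hole filling** — 4-connected background components strictly smaller
  than `max_hole_area` (default 40 px ≈ half the SS minimum cell area) and
  not touching the border become foreground; idempotent by construction.
* **Star-convex splitting** — interiors (filled tissue minus membranes) are
  split by markers at distance-transform peaks separated by
  `expected_radius` (default 8 px), grown by watershed on the negated
  distance transform, then clipped to the pixels radially visible (64 angle
  bins) from the instance's centroid — or its distance-transform maximum
  when the centroid falls outside — so every instance is star-convex about
  its center. A pre-trained star-convex detector can be plugged in through
  the `pretrained` backend (any object with `predict_instances`); the
  built-in fallback keeps the test suite free of downloaded weights.
* **Area filter** — instances below 100 px (stratum granulosum) or 50 px
  (stratum spinosum) are removed; instances exactly at the threshold are
  kept; labels are recompacted.

## Evaluation

d-accuracy: minimum-total-cost one-to-one assignment (Hungarian algorithm)
on the predicted-vs-true center distance matrix; assigned pairs farther than
d (default 10 px, ≈ half a typical keratinocyte diameter at 1 µm/px — the
radius is configurable and always reported) are discarded. Degenerate
conventions: precision is 1 when there are no predictions and nothing to
find, 0 when there are no true positives among predictions. Per-image F1 is
aggregated as median and standard deviation (ddof = 0) on a 0–100 scale.

## Benchmark problem sizes

The package's standing benchmarks run at desk scale: post-processing
recovery uses ten 256×256 replicates with 20% membrane dropout; the
end-to-end run trains on 32 images (12 raw-like, 12 enhanced, 8 binary) at
64×64 for 200 epochs with batch 4, and evaluates on six held-out renderings.
These sizes are the package's own validation recipe; the architecture and
pipeline also run at the published scale (256×256, hundreds of images,
thousands of epochs) given proportionally more compute.

## Known limitations

* The NumPy networks are single-threaded CPU code; published-scale training
  is supported in principle but slow.
* The texture veto's unsupervised fallback assumes noise-dominated windows
  are a minority; a trained classifier should be supplied when they are not.
* The alpha-shape floor couples contour closure to the expected cell size;
  tissues with genuinely sub-cellular concavities would need a smaller
  `min_alpha`.
* d-accuracy scores centers only; boundary quality is deliberately out of
  scope.
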