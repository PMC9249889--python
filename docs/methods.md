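# Methods

## The measurement being simulated

A 3D imaging flow cytometer sections each flowing cell with a fast-scanning
light sheet (200 kHz) while pinhole spatial filters on the side and forward
image planes encode spatial position into the timing of photomultiplier
signals. Decoding those temporal signals with the (bijective)
temporal–spatial mapping yields, per cell, a 40×40×40-voxel side-scatter
stack (1 µm/voxel) and an 80×80-pixel transmission image (0.5 µm/pixel),
both spanning a 40 µm field of view. `dualifc.scanner` implements the
mapping in its idealized form: the scan axis is fastest, the pinhole
(depth) axis next, the flow axis slowest; there is no crosstalk, blur or
desynchronization, so decode(encode(v)) = v exactly and intensity is
conserved. Detector noise is available as an additive Gaussian term.
Physical optics (deflector, objectives, point-spread functions, digitizer)
are out of scope; with a 1 µm voxel column per 200 kHz scan period the
synchronized flow speed is 0.2 m/s.

## Phantom cells

Each phantom is an ellipsoid with lognormally distributed semi-axes
(healthy means 9×8×7 µm, σ_log = 0.08), Haar-random orientation, and a
center jittered uniformly within ±4 µm of the field center (cells are
hydrodynamically focused, so one centered cell per image; phantoms that
would clip the field of view are resampled, up to 25 times). The internal
texture is a Gaussian random field — white noise smoothed at the
correlation length, mapped through the normal CDF so its marginal is
uniform on [0, 1] — scaled by a contrast amplitude around mid-gray.
Vacuoles are spheres placed uniformly inside the (shrunken) ellipsoid and
rendered as intensity/attenuation depressions (factor 0.2), mimicking
nuclear vacuolation.

Rendering: the side-scatter stack is the texture field restricted to the
voxelized mask; the transmission image is I₀·exp(−∫µ dz) with
µ = base_attenuation · (1 + coupling·(texture − 0.5)) inside the cell,
integrated along the flow-normal axis and bilinearly resampled to the
0.5 µm pixel grid. Small additive Gaussian noise (σ = 0.005 of I₀ in 2D,
0.01 in 3D) is clipped at zero.

Class presets (the study conditions):

| preset | healthy | diseased | purpose |
|---|---|---|---|
| `default` | corr. len 2.5 µm, contrast 0.7, 1 vacuole, µ₀ = 0.04/µm | volume ×1.10, corr. len 1.2 µm, contrast 0.85, 4 vacuoles, µ₀ = 0.045 | qualitative disease directions: higher entropy, lower homogeneity/energy, slight volume increase |
| `strong` | corr. len 3.0, contrast 0.5, no vacuoles | volume ×1.30, corr. len 1.0, contrast 1.0, 5 large vacuoles, µ₀ = 0.06 | strongly separable cohort for classifier-recovery checks |
| `texture_phase` | +phase | −phase | class difference invisible to the feature panel (below) |

No quantitative healthy-vs-diseased effect sizes are available for the
underlying biology, so the `default` preset is calibrated only to
reproduce the qualitative directions (it does: over 200 cells/class the
extracted diseased/healthy volume ratio recovers the configured 1.10
within 5 %, and mean 3D entropy is higher / homogeneity and energy lower
in the diseased class). The generator emulates the statistical structure
of a donor cohort — two healthy and two diseased subjects per cell type,
independent per-subject RNG streams spawned from the master seed — but not
optical artifacts, debris, doublets, or real biological heterogeneity;
passing tests demonstrate method correctness and recovery of configured
effects, not clinical performance.

### The texture-phase preset

To probe what raw images carry beyond the feature panel, the
`texture_phase` preset makes the two classes differ **only in the spatial
phase of a periodic texture**: a 3D block checkerboard (2-voxel blocks,
period 4) whose bright/dark phase relative to the voxel lattice flips with
the class, plus i.i.d. uniform intensity wiggle. A phase flip is a 2-voxel
translation of the pattern; co-occurrence counting is translation-
invariant, first-order statistics of the symmetric bimodal pattern are
phase-free, and cell geometry is independent of the pattern — so all 55
features are blind to the class up to the random mask/lattice alignment
(the center jitter spans a full period). The raw stack shows the phase
directly, and the 2× average-pool stem of the desk-scale fused model
aligns with the 2-voxel blocks, so the contrast survives downsampling.
Transmission texture coupling is zero in this preset: the 2D images carry
no class signal at all. On this cohort the seven conventional classifiers
score at chance while the fused model, reading the raw stacks, does not —
the ordering the acceptance checks assert.

## Preprocessing

Background removal zeroes elements below τ·max (τ = 0.05 by default,
per-image, with an Otsu option and a dataset-global switch); transmission
images are first converted to absorbance (max − I) so the cell, not the
illuminated background, is foreground. Each modality is then normalized by
its own dataset-wide maximum (transmission and side-scatter have different
dynamic ranges), which is idempotent. Class balance is enforced by drawing
exactly n pairs per subject without replacement (deterministic given the
seed, subjects processed in sorted order); the canonical cohort size is
5000 × 4 subjects = 20,000 pairs. Balanced sampling returns an index-level
view, so subsampling never copies pixel data.

## The 55-feature panel

The exact identities of the features are fixed by this package's
registry: per modality, geometric
morphometry (10 in 2D, 9 in 3D), five first-order intensity statistics,
and 13 co-occurrence (Haralick) statistics — 28 + 27 = 55, in a fixed
column order that is part of the CSV contract. Choices of note:

- Segmentation: largest connected component above τ·max, holes filled
  (8-connectivity in 2D, 26 in 3D).
- 2D perimeter uses the Crofton estimate; 3D surface area uses a marching-
  cubes isosurface of the lightly smoothed mask (Gaussian σ = 0.8 before
  meshing removes the ~8 % staircase bias of a binary isosurface; a
  face-counting estimator is kept as a test oracle only). Principal axes
  come from the eigendecomposition of the voxel covariance
  (axis length = 2√(5λ), exact for solid ellipsoids). Degenerate
  single-pixel masks report one pixel pitch.
- Quantization: 32 gray levels (configurable), linear binning over the
  masked min–max range; background carries a sentinel level excluded from
  pair counting, since texture is computed on background-removed images.
- GLCMs are symmetric (added transpose), normalized to unit sum; the 2D
  direction set {0°, 45°, 90°, 135°} × d ∈ {1..4} (16 matrices) steps d
  pixels along the direction vector (chessboard convention), and the 3D
  set is the 13 unique 26-neighborhood directions × offsets {1..4} — 52
  matrices, the arithmetic consequence of 13 × 4. The 13 statistics
  (energy, entropy, contrast, correlation, homogeneity, maximum
  probability, variance, sum average, sum entropy, difference entropy,
  difference variance, cluster shade, cluster prominence) use base-2
  entropies with 0·log 0 = 0; statistics, not matrices, are averaged
  across configurations, so the 2D average is exactly invariant under 90°
  image rotation. A displacement with no valid pairs is skipped with a
  warning; if all are skipped, an error is raised.
- Z-scoring follows r_n = (r − mean)/σ with population σ; fitted
  parameters are stored (JSON sidecar) and reapplied to held-out data.
  Constant columns map to zeros with a warning.

The GLCM implementation is verified exactly against an exhaustive
brute-force pair-counting oracle on every configured 2D and 3D
displacement, and against scikit-image's `graycomatrix`/`graycoprops`
where conventions overlap (scikit-image mirrors the diagonal angles and
rounds diagonal offsets to Euclidean distance, so the overlap is axial
angles at all distances plus diagonals at d = 1; contrast, correlation and
ASM agree to 1e-6).

## Conventional-classifier benchmark

Seven standard scikit-learn classifiers (logistic regression, k-NN with
k = 15, RBF SVC, random forest, gradient boosting, Gaussian naive Bayes,
Gaussian process) are evaluated under stratified 4-fold cross-validation.
The model identities are fixed by this package.
Folds are stratified on (subject, class): each subject's cells are dealt
into k near-equal parts with the remainder rotating per class, so per-fold
class counts stay within one of exact proportionality and every fold holds
≈25 % of each subject's cells. Z-score parameters are fitted on training
folds only. The Gaussian process classifier's training set is capped
(default 2000 points) for cubic-cost tractability. Balanced accuracy is
the arithmetic mean of per-class recall; precision/recall/F1 are
macro-averaged from the per-fold confusion matrices. An 80/20 stratified
holdout split is provided as an alternative mode; 4-fold CV is primary.

## Fused UNet autoencoder-classifier

Two UNet branches — 2D for transmission, 3D for side-scatter — share one
architecture family: `depth` encoder levels of 3^d conv + ReLU with 2×
max-pooling between levels and channel widths doubling from
`base_channels` (defaults 16 in 2D, 8 in 3D, depth 3); the decoder mirrors
with nearest-neighbor upsampling, a 1×1 channel-reduction conv, skip
concatenation and a 3^d mixing conv; a final 1×1 conv yields a
reconstruction with exactly the input shape. Each bottleneck is average-
pooled onto a coarse 5-per-axis grid and flattened; the two latents are
concatenated into a single affine layer and softmax. The coarse grid
(rather than a fully global average) is deliberate: a global average
discards all spatial layout of the bottleneck and is provably blind to
contrasts like the texture-phase preset, while a 5³/5² grid keeps the
classifier head small and retains coarse position. Weights use He fan-in
initialization.

The loss is L = w₂·L_CE + (1 − w₂)·L_MSE with
L_MSE = (1/N) Σⱼ [ w₁/M_2d Σᵢ(x − x̂)²_2d + (1 − w₁)/M_3d Σᵢ(x − x̂)²_3d ],
M_2d = 6400 and M_3d = 64,000 the flattened image sizes; w₁ = w₂ = 0.5 by
default (neutral weighting; both weights are config-exposed). Cross
entropy uses the natural logarithm with probabilities clamped at 1e-12.
The default optimizer settings are Adam with β₁ = 0.99, β₂ = 0.9999
(an unconventional pairing, kept as the reference protocol's values; a
flag switches to the conventional 0.9/0.999), learning rate 1e-5 for
epochs 1–5 then 5e-5, halved whenever validation balanced accuracy fails
to improve by 1e-4 for five consecutive epochs, 50 epochs, batch 32.
"Validation metrics stopped improving" is interpreted as validation
balanced accuracy with patience 5. During cross-validation the held-out
fold serves as the validation set that drives the plateau rule and is then
summarized in that fold's confusion matrix.

The network is plain numpy with hand-written backpropagation.
Convolutions use a shift-and-accumulate formulation (one channel
contraction per kernel offset via `einsum`), which avoids materializing
im2col matrices and is the fastest option at these channel counts on one
core. Gradient correctness for the full fused model — both branches,
skips, latent fusion, and all three loss terms — is verified against
central finite differences (relative error < 1e-4, float64). Training is
bit-reproducible given the seed: initialization, shuffling and noise all
derive from it.

**Desk-scale preset.** CPU-scale experiments use quarter-width channels
(4/2), a 2× average-pool stem in front of each branch with a matching 2×
upsample before the output conv (the trunk runs at 40² / 20³ while
reconstructions keep the acquisition shapes), 10 epochs, conventional
Adam betas, and a proportionally raised two-stage schedule (1e-3 for two
epochs, then 3e-3, plateau rule unchanged). Synthetic cohorts for the
classifier-recovery experiments are 800 cells across 4 pseudo-subjects
(200 each); with these settings one 4-fold cross-validation takes roughly
7–8 minutes on one CPU core. At the reference settings (full width, 50
epochs, 20,000 cells) the same code is GPU-scale work and is not run in
the test suite.

## Numerical and degenerate-input conventions

Correlation of a zero-variance GLCM is 1; constant masked regions quantize
to level 0; constant feature columns z-score to zeros (with a warning);
empty foreground raises a segmentation error; an all-zero image passes
background removal unchanged; maximum-pooling gradients split equally
among tied maxima; reconstruction outputs are linear (no output
nonlinearity). HDF5 stores images float32, chunked per cell, gzip; the
feature CSV column order is validated on read; every pipeline manifest
embeds the configuration hash and master seed.

## Known limitations

- The phantom is a single convex ellipsoid: no doublets, debris, irregular
  membranes, or subcellular organelle structure beyond texture + vacuoles.
- The scan model is noiseless and perfectly synchronized; reconstruction
  artifacts of a real instrument are absent.
- Feature-panel identities are fixed by this package's registry; the 28/27
  per-modality split is part of the contract.
- Donor-scale F1 values cannot be reproduced without donor images; the
  classifier-recovery tests are properties on synthetic cohorts (recovery
  of configured effects, ordering of image-based vs feature-based models,
  permutation-null behavior), not re-measurements of donor-scale scores.
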