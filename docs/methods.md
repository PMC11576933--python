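# Methods

## The problem and the approach

Newborn brain MRI arrives at many voxel sizes (roughly 0.5–1.0 mm in-plane)
and with much larger head-pose variation than adult imaging. The usual
remedies — resampling every image to a fixed grid, and augmenting training
images and label maps with external affine transforms — both interpolate:
resampling moves the prediction off the native acquisition grid, and
external augmentation forces lossy nearest-neighbour interpolation of the
discrete label maps (or soft one-hot interpolation, at the cost of soft
targets).

`neoseg` implements the alternative: a UNet-style encoder–decoder whose
*first* and *last* scale transitions are replaced by a four-degree-of-freedom
(4-DOF) affine transform module that acts on **feature maps** in latent
space. At the first transition the module maps native-resolution features
onto a fixed inner physical scale (`res_inner`, default 0.8 mm), optionally
composed with a per-sample in-plane rotation θ, 2D translation T, and a
Gaussian perturbation α of the scale factor

    SF = res_inner / res_native + α,        α ~ N(0, 0.1).

At the last decoder transition the *exact inverse* of the recorded matrix is
applied, so the per-class probabilities always live on the input voxel grid
— no resampling anywhere outside the network, and labels are never
interpolated. At inference θ = T = α = 0 and the module reduces to pure
resolution normalization.

Three parameter-equal variants of the same macro-architecture are built:

| variant  | first/last transition                          |
|----------|------------------------------------------------|
| `pool`   | 2×2 max-pool / index-unpool (fixed-resolution baseline) |
| `scale`  | latent transform, scaling only (resolution normalization) |
| `affine` | full 4-DOF latent transform                    |

Ablation arms add external augmentation (`+ext`: nearest-neighbour labels;
`+ext_soft`: bilinear interpolation of one-hot label channels) and, for the
`pool` arm only, external scaling in [0.8, 1.15] — the normalizing variants
make external scaling redundant.

## Architecture

Five encoder and five decoder blocks around a bottleneck. The first two
encoder blocks are *input* competitive dense blocks (pre-IDB, IDB:
BN–Conv–BN head, then the competitive scheme); all others are competitive
dense blocks (CDB): four PReLU–Conv(3×3, same padding)–BN sub-layers whose
normalized outputs compete through elementwise `maxout` with the running
skip (maxout always follows BN, which keeps the competing branches on a
common scale). Scale transitions other than the first/last are 2×2
max-pooling with recorded indices, mirrored by index-unpooling; pooling is
ceil-mode (odd edges padded with −inf) so the fixed five-level depth also
works on small desk-scale slices. Decoder blocks merge the encoder skip by
maxout; the final post-CDB *concatenates* the native-space pre-IDB skip with
the inversely-transformed decoder features, applies a CDB, a 1×1 classifier
convolution, and a per-pixel softmax.

The scale transitions carry no learnable parameters, so all three variants
have identical parameter censuses and interchangeable checkpoint structures
(asserted by tests).

Defaults where the recipe leaves the choice open: 64 filters per block
(tests and the desk-scale benchmark use 8), single-channel slice input,
PReLU slopes initialized at 0.25, batch-norm momentum 0.1 and eps 1e-5,
Kaiming fan-in weight initialization matched to the PReLU gain,
seed-controlled throughout.

### Geometry conventions

Pixel centers at integer coordinates, 0-based, (row, col) order. The 4-DOF
matrix is composed as `T(center)·S·R(θ)·T(−center)·T(t)` with the rotation
center at the map's geometric center `((H−1)/2, (W−1)/2)`; positive θ
rotates the +row axis toward the +col axis. Because the translation enters
on the native (source) side of this composition, a draw in native pixels
realizes the same physical displacement at every resolution. Sampling grids
use pull semantics (each output pixel stores its source coordinate);
out-of-bounds reads are zero for features and background (0) for
nearest-neighbour label lookups; half-way coordinates round to the higher
index. The bilinear sampler is also materialized as a sparse matrix so the
per-channel latent sampling is a single matmul with an exact transpose for
the gradient.

The inner grid size is `round(native_shape · SF)` per axis with the
*unaugmented* SF, so one mini-batch shares an inner grid while each sample's
α still perturbs its sampling matrix; a lower bound of 16 px keeps the four
remaining pooling levels valid, and SF itself is clamped at 0.05 (α is an
unbounded Gaussian draw).

## Loss

The composite loss is a per-pixel-weighted logistic term plus a soft-Dice
term over classes,

    L = − Σ_{l,i} ω_i y_{l,i} log p_{l,i}  −  Σ_l 2⟨p_l, y_l⟩ / (Σ p_l + Σ y_l),

with the Dice ratio defined as 0 where its denominator vanishes and
probabilities clamped at 1e−7 inside the log. The weight map decomposes as

    ω = ω_medianfreq + ω_gradient + ω_GM + ω_WM/Sulci:

median-frequency class balancing (computed once over the training set and
cached; absent classes get weight 0, not ∞), the magnitude of the 2D label
gradient (boundary emphasis), and two binary morphological masks around the
cortex — cortex minus its erosion (the outer, partial-volume-affected
cortical band) and dilation minus cortex (adjacent thin white-matter strands
and deep sulci). The scalars multiplying the last three components and the
structuring radius default to 1 and are exposed in `LossConfig`.

For optimization the two terms are balanced (`reduction="balanced"`: the
logistic sum is divided by the pixel count and the Dice sum by the class
count) so neither term numerically swamps the other regardless of batch
size; the raw-sum form is kept for the loss-identity contracts.

## Training and inference

One network instance per anatomical plane; 2D slices with entirely-background
label maps are filtered out; sagittal slices are remapped to the merged
(non-lateralized) label set since that view cannot see laterality. Batches
group slices of equal native resolution. Optimization is Adam with β₁ = 0.95
(the recipe's "momentum 0.95", compensating the small batch size of 16),
peak learning rate 0.001 under cosine annealing with warm restarts (first
period 10 epochs, each subsequent period doubled — restarts at cumulative
epochs 10, 30, 70), early stopping on validation mean foreground DSC
(patience 10 evaluations, best state restored). Intensity augmentation
transforms each batch with probability 0.4 by one of {bias field, gamma,
ghosting, spiking, blur, Gaussian noise}; its sub-operation constants are
conventional values exposed in `IntensityAugConfig`. Everything — weight
init, batch order, every augmentation draw — derives from one seed; two runs
with the same seed produce bit-identical loss curves.

Inference runs slices at their native resolution (spacing must come from
the volume header; it is never assumed) and reassembles per-class
probability volumes on the exact input grid. 2.5D view aggregation averages
the three per-plane probability volumes with weights (0.4, 0.4, 0.2) — the
sagittal weight halved for its missing lateralization — after splitting each
merged sagittal class probability equally between its two lateralized
children, letting the lateralizing views resolve the side; argmax gives the
final labels. Label harmonization (merge/remove/mask against a reference)
and a distance-transform utility for lateralizing intracranial background
are provided for cross-protocol comparisons.

"Modified Adam" in the recipe is under-specified; this package implements
standard Adam with β₁ = 0.95 and exposes the betas.

## The numerical engine

The grading-free design constraint of this package is that the full
network stack — convolution, batch norm, PReLU, maxout, pooling with
indices, the sparse bilinear sampler, softmax, the composite loss, Adam —
runs on a small tape-based reverse-mode autodiff engine over NumPy
(`neoseg.autodiff`). Convolutions are im2col + BLAS matmuls with a
nine-slice col2im for the input gradient; batch norm is a fused op; network
weights run in float32. Every operation's gradient is checked against
central finite differences in float64, including one end-to-end check
through the whole network and loss. Exact ties in maxout split the gradient
equally between branches.

## Synthetic phantoms

The generator produces analytic "heads": a folded cortical ribbon (an
ellipsoid shell whose outer boundary is modulated by a low-order angular
fold pattern) around a white-matter core containing two lateralized
subcortical blobs, posed by a 3D rotation and translation, rasterized at any
resolution by evaluating the shape functions at voxel centers — labels are
therefore *exact* at every pose and resolution and are never produced by
resampling (the property the latent-transform method is about). The voxel
grid is odd-sized and symmetric about the head center so 0.5 mm and 1.0 mm
grids share centers at integer millimetres and axis-aligned 90° pose
rotations equal array rotations exactly (laterality ties on the midplane are
snapped to avoid float ambiguity). Intensities are per-class means (T2w-like
contrast) under a smooth multiplicative scanner-frame bias field plus
Gaussian noise; anatomy parameters are jittered per subject so class
frequencies vary across the cohort.

Dimensions are miniature (head semi-axes ≈ 7.2 × 6.0 × 5.6 mm in a 20 mm
field of view) so that desk-scale CPU training is feasible; the in-plane
anisotropy is deliberate, keeping head orientation identifiable from a
single slice at any rotation. The ribbon (≈ 2.1–2.5 mm) stays ≥ 2 voxels at
the coarsest resolution. Because the frame is miniature, experiment configs
scale the translation-augmentation range to 0–2 px, matching the *relative*
displacement of the full-size recipe's 0–15 px; the library defaults keep
the recipe's numbers.

What the phantoms do **not** emulate: realistic cortical folding geometry
and its spatial frequency spectrum, tissue-contrast changes with
post-menstrual age, motion artifacts, partial-volume mixtures beyond what
rasterization induces, and real label noise. Passing the benchmark therefore
shows the machinery behaves as designed under controlled conditions, not
that a clinically useful model results from these tiny runs.

## The desk-scale benchmark (`neoseg.experiments`)

Fixed study conditions: 57 phantoms (40 train / 7 val / 10 test), two
resolutions (0.5, 1.0 mm) equally represented, in-plane head rotations
±45°, coronal-plane training, 8 filters, 18 epochs (~160 optimizer steps),
slice subsampling (every 6th training slice). On these conditions the
ablation orderings of held-out mean foreground DSC —
`affine ≥ scale+ext ≥ pool+ext` and `affine ≥ affine+ext` — are evaluated
over three seeds, and the rotation-consistency probe compares the
segmentation of each test phantom with the counter-rotated segmentation of
its 90°-rotated twin.

Known limitation, deliberately left visible: ~10²–10³ NumPy-engine
optimizer steps are one to two orders of magnitude short of convergence for
this architecture. The ablation *orderings* are already stable at this
budget (the resolution-normalizing and internally-augmenting variants win
consistently), but absolute accuracy (held-out DSC ≈ 0.3–0.5, ≈ 0.8 after
~10 minutes of single-arm training) and especially rotation *consistency*
(≈ 0.25–0.37, rising slowly) remain far from their converged values —
rotation robustness is the slowest property to emerge because the
native-space input blocks are not rotation-equivariant and the deep layers
must learn it from the internal augmentation. The benchmark reports these
numbers as measured.

## Degenerate inputs and tie-breaks (summary)

* SF ≤ 0.05 → clamped with a warning; non-positive resolutions → error.
* Inner grid < 16 px → error (input too small for the five-level net).
* Nearest-neighbour ties → higher index; maxout ties → gradient split.
* Empty label map → error in median-frequency weighting; absent classes →
  weight 0.
* DSC: both masks empty → 1, exactly one empty → 0. ASD: empty mask → NaN
  (reported missing). All-zero paired differences → Wilcoxon undefined,
  flagged and excluded from the BH family.
* Soft labels: per-pixel renormalization only where channel mass > 0;
  zero-mass pixels become background.
* Unmapped labels in harmonization → error listing the offenders; volumes
  without header spacing → error (never a silent 1 mm default).
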