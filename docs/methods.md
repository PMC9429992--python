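# Methods

## Problem setting

Cerebrovascular vessels in 3D time-of-flight MR angiography (TOF-MRA) are
bright, thin, winding tubular structures occupying well under 5% of the
scan volume. Dense supervised segmentation of them faces two coupled
problems: extreme class imbalance, and the need for genuine 3D context to
follow non-planar vessel paths. This package implements a segmentation
pipeline built around three ideas:

1. **an anatomical occupancy prior** that focuses attention on regions
   where vessels plausibly run,
2. **a centerline-aware loss** that rewards preserved connectivity rather
   than raw voxel overlap alone, and
3. **an adversarial feature-matching discriminator** that pushes predicted
   vessel regions to look statistically like true vessel regions across
   scales.

Inputs are assumed brain-extracted and affinely co-registered to a common
template upstream; the package neither performs nor emulates those steps
(`assert_preregistered` documents the hook).

## Ground-truth rendering

Public vessel annotations are centerline points with per-point radii and no
local direction, so each point is rendered as an isotropic sphere of its
radius (in mm; anisotropic grids give per-axis scaled footprints), and the
sphere-chain union approximates a tube. A voxel is vessel when its center
lies within the radius of some point; the voxel containing the point is
always set so degenerate radii still leave a mark. The raw union is
scalloped, so a refinement pass — Gaussian smoothing (default sigma 1
voxel), re-thresholding at 0.5, and erosion with the 3×3×3 discrete unit
ball — restores tubular morphology. Sigma and the structuring element are
configurable; the defaults are the smallest values that fuse scalloping
without destroying radius-1 vessels. Whether stored radii are mm or voxels
is dataset-specific and is therefore a required reader argument.

## Occupancy prior

After registration, vessels occupy stereotyped positions, so the per-voxel
count of vessel occupancy over the training cohort is an informative prior.
Counts below 5% of the cohort are nullified as annotation noise: with 36
training subjects, a voxel seen once (2.8%) is removed and one seen twice
(5.6%) survives; the comparison is strict (`count/n < min_fraction`
removed). The network consumes the prior as a normalized frequency in
[0, 1] (not raw counts), one-hot encoded like the ground truth, so gate
inputs live on the same scale as the scan; this choice is recorded in the
atlas sidecar. Each cross-validation fold builds its prior from its
training subjects only and freezes it for validation and test.

## Preprocessing

Scans are clipped to [0, 350] scanner units (suppressing the bright noise
tail), linearly rescaled between their 10th and 99th intensity percentiles,
clipped to [0, 1], and divided by the resulting maximum. The published
description of this step does not fix the operation order; this order is
the one that guarantees an output in [0, 1] with maximum exactly 1, and is
recorded here as the package's reading. Percentiles use linear
interpolation over the whole (or brain-masked, when a mask is supplied)
volume.

## Patch regime

Training draws random 80³ patches (configurable) uniformly from the brain's
tight bounding box, padding symmetrically when the box is smaller than the
patch. Inference tiles the zero-padded volume with non-overlapping windows
of the same size and reassembles; every voxel is written exactly once.
Augmentation applies left-right flips (p=0.5), rotations about a random
axis pair (p=0.5, ±15°), and zoom in [0.9, 1.1] (p=0.3) identically to
scan, ground truth and prior, and multiplicative gamma noise (p=0.3,
mean-1 Gamma with concentration 50) to the scan alone. All resampling is
linear; the ground truth is re-binarized at 0.5 afterwards. Nearest-
neighbour resampling was rejected because it aliases binary tubes badly
(a 1.1 zoom changed sphere volume by ×1.105 instead of the analytic
×1.331; linear + re-binarize gives ×1.325).

## Networks

Both networks run on a small reverse-mode autodiff engine written in numpy
(`angioseg.nn`): 3D convolutions are computed in the Fourier domain (real
FFTs of the padded input; kernel spectra via per-axis DFT contractions
since kernels are tiny; weight gradients recovered at the k³ lags by an
inverse-DFT contraction), with 1×1×1 convolutions as plain channel
matmuls; stride-2 is stride-1 plus subsampling. This keeps the whole
pipeline importable with a scientific-Python stack only.

**Generator.** A four-level 3D U-Net over the scan patch (channels double
per level from a configurable base; two 3³ convolutions with instance
normalization and rectified activations per block; average-pool
downsampling; nearest-neighbour upsampling) runs in parallel with a second
U-Net over the two-channel prior patch. Five anatomical attention gates
combine the streams: one per encoder skip (3), one at the bottleneck, and
one at the final decoder scale. Each gate projects both streams through
1×1×1 convolutions, concatenates their placewise sum and product with both
projections, mixes with a joint 1×1×1 convolution, and multiplies the
sigmoid weight map into the scan features. The joint convolution is
zero-initialized so every gate starts neutral (weight 0.5 everywhere) and
learns to open or close; randomly initialized gates were observed to
saturate (sigmoid overflow, dead gradients) and occasionally freeze
training. The head is a per-voxel two-channel softmax. The prior branch
may be configured encoder-only.

**Discriminator.** A purely convolutional five-scale hierarchy (3³
stride-2 convolutions, leaky rectified activations, no normalization, no
real/fake head). Its per-scale feature maps are the only output: the
adversarial signal is entirely the feature-matching loss below, so the
discriminator is a learned multiscale statistic of vessel-masked scan
appearance.

## Losses

With reference one-hot R, soft prediction P, class index l and voxel
index n:

**Generalized Dice loss.**
`ℓ_gdl = 1 − 2 Σ_l w_l Σ_n R_ln P_ln / Σ_l w_l Σ_n (R_ln + P_ln)` with
`w_l = 1/(Σ_n R_ln)²` — weights inversely proportional to squared class
volume, so the scarce vessel class dominates. An empty class would make
the weight infinite; the squared volume is replaced by ε = 1e−5 for empty
classes only, so non-degenerate inputs evaluate exactly (the 2×2×2
hand case reproduces 0.25 to 1e−9).

**Centerline Dice.** Skeletons are extracted by iterative soft
morphological thinning: erosion with the 6-neighbour cross (the minimum
over three axis-aligned length-3 min-pools), dilation with the 3×3×3 cube,
k iterations of erode/open/residual accumulation. On the binary ground
truth this is exactly hard thinning; on soft predictions it is
differentiable. Topology precision `|S_P ∩ R|/|S_P|` and sensitivity
`|S_R ∩ P|/|S_R|` (soft product sums) combine as a harmonic mean; the
training loss is 1 − clDice, so minimization is meaningful; 0/0 degrades
to loss 1. The cube/cube erosion-dilation pair was tried first and
distorted fat-tube skeletons (disagreement with a classical thinning
oracle up to 0.38); the asymmetric pair agrees with
`skimage.morphology.skeletonize` to ≤0.05 (mean 0.01) on vessel-calibre
tube phantoms across a 60-seed robustness scan. The default iteration
count k = 10 covers radii up to 10 voxels; scaled-down experiments use
k = 3–4 for their ≤3-voxel tubes.

**Feature-matching loss.** `ℓ_mae = (1/L) Σ_i ‖f_i(x∘P_v) − f_i(x∘R_v)‖₁`
over the discriminator's L = 5 scales, where ∘ is the voxelwise product
masking the scan with each vessel map. The L1 norm is realized as the mean
(not sum) of absolute differences per scale so the loss scale is
independent of feature-map size. The generator minimizes it; the
discriminator maximizes it.

**Combined objective.** `ℓ = ℓ_gdl + ℓ_cld + ℓ_mae`, unweighted, each
averaged over the batch. Baselines and pretraining use `ℓ_gdl + ℓ_cld`.

## Training protocol

Phase 1 pretrains the generator on `ℓ_gdl + ℓ_cld` (Adam, β₁ = 0.9,
initial learning rate 5e−3, batch 6, up to 100 epochs, early-stopped
pre-convergence). Phase 2 trains adversarially (up to 150 epochs): each
generator step minimizes the combined loss; every third step the
discriminator takes one ascent step on ℓ_mae (learning rate 1e−4). The
decayed generator learning rate at the end of pretraining carries into
phase 2. Both phases monitor validation vessel Dice; on a plateau
(min_delta 1e−3, patience 5) learning rates halve, and training stops
early after 15 plateau epochs. Within each epoch the subject list is
iterated twice with fresh random crops. Two stabilization measures are the
package's own: gradient-norm clipping on the discriminator (max-norm 1) —
its objective is an unbounded maximization — and a loose clip (max-norm 5)
on the generator. Ablation arms are pure configuration: `unet` (no prior,
no discriminator), `unet_prior` (prior + gates, no discriminator), `adv`
(everything), `adv_noprior`, `gdl_only` and `cld_only` (single
segmentation-loss variants of the adversarial model).

## Synthetic phantoms

The phantom generator emulates the data regime the method assumes — and
only that: bright sparse branching tubes on darker tissue. Geometry is a
tapering random walk (step 0.5 voxel, direction jitter 0.25, multiplicative
taper, branch probability 0.05/step, children at 0.8× parent radius, so
radii are monotone non-increasing root to tip); trees are added until the
vessel-fraction cap (5%) would be exceeded. Dense ground truth is rendered
by the same sphere renderer used for real annotations — a deliberate
cross-module consistency point. Intensity is background 80 / vessel 300 on
the pre-clip scanner scale (so the [0, 350] clip window is exercised),
partial-volume Gaussian blur (sigma 0.7 voxel), and mean-1 gamma noise
(concentration 100, ≈10% intensity noise). Cohorts share a trunk grown
from the cohort seed plus member-specific trees, making the occupancy
prior informative (trunk counts = n). What phantoms do **not** model:
flow-related signal variation, anatomically realistic circle-of-Willis
geometry, registration error, annotation noise, or peripheral veins —
passing phantom tests therefore demonstrates mechanical and statistical
correctness of the pipeline, not clinical performance.

## Scaled-down study conditions

Full-scale training (fivefold, 42 subjects, 448×448×128 scans, GPU-weeks)
is out of desk scope. The end-to-end experiments in the test suite and
acceptance script use: 20-member phantom cohorts of 32³ voxels (18 train /
1 validation / 1 held-out), tube radii 1.5–2.5 voxels at 0.5 mm spacing,
random 24³ training crops, batch 6, base width 4 for both networks,
skeleton iterations 3, six pretraining plus nine adversarial epochs.
Held-out evaluation runs the generator on the full 32³ volume in a single
window: a phantom fits in one window, and instance-normalization
statistics of heavily zero-padded partial windows were observed to corrupt
border predictions, which the single-window inference avoids (real-scale
inference tiles with the training patch size as usual). Held-out scores at
this scale are seed-dependent — some seeds pass through a transient basin
in which the centerline-Dice term is satisfied while the volumetric term
lags — so stochastic checks use three replicate seeds with a majority or
median rule.

## Numerical choices

float32 throughout the networks; float64 in the numpy-facing loss
evaluators. FFT sizes are padded to fast lengths. Max-pool gradients route
to the first argmax of each window; elementwise-minimum gradients to the
first argument on ties. Binarization of soft predictions is channel argmax
(threshold 0.5 on the vessel channel). Hausdorff distances are computed
over full vessel voxel sets (not surfaces, not percentiles) via Euclidean
distance transforms with physical spacing, equal to the brute-force
all-pairs definition; empty sets give +inf and are excluded from fold
aggregates with a warning. Empty-prediction precision is reported as 0
with a degeneracy flag.

## Known limitations

- The desk-scale experiments are far below the operating point of the
  original protocol (tens of epochs on thousands of patches of 80³ with
  16–128 channels); conclusions about the *relative* merit of loss
  components at that scale do not necessarily transfer down. In
  particular, at this scale the GDL-plus-feature-matching ablation
  converges faster than the full three-term loss on high-contrast
  phantoms, because the centerline-Dice term is satisfiable by thin,
  centerline-concentrated soft predictions before the volumetric term has
  converged; the acceptance suite measures this ordering honestly rather
  than asserting the large-scale expectation.
- The soft skeleton and a classical thinning oracle diverge on tubes much
  fatter than the vessel calibre (radius ≳ 3 voxels).
- The autodiff engine is single-threaded numpy; it is adequate for the
  problem sizes above (≈2 s per training step at 32³) and makes no claim
  to GPU-class performance.
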