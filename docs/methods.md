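# Methods

`contourpro` analyses the contour images produced by comprehensive
two-dimensional gas chromatography–time-of-flight mass spectrometry
(GC×GC–TOFMS).  A contour image is a colormapped raster in which the x
axis is the first-dimension retention time, the y axis the
second-dimension retention time, and color encodes aggregate ion
intensity.  The package treats the contour image itself as the unit of
analysis — untargeted, holistic profiling — rather than extracting
individual peaks.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not demonstrate.

## Representative contours (AFRC)

One image per study group is built by the exponentially weighted
accumulator

    afrc(x, y) ← (1 − α) · afrc(x, y) + α · frame(x, y),

applied cyclically over the group's images wherever the incoming frame
carries content.  This is the running-average background model
(`accumulateWeighted` in OpenCV terms): features present in most
replicates are reinforced on every pass, a feature present in a single
outlier decays geometrically, and the result is a group representative
that required no signal/noise decisions.

Choices the update rule leaves open, fixed here:

* **Initialization** — the first frame (the accumulateWeighted
  convention).  Zero-initialization would bias the output dark at any
  finite cycle count.
* **α (weight accumulation factor)** — default 0.05.  With 15 images per
  group and 3 cycles (45 updates), the initializer retains
  (1 − 0.05)⁴⁵ ≈ 0.10 influence, so every frame contributes while no
  single frame dominates.  No reference value exists for α; it is a
  smoothing constant, not a fitted parameter.
* **Cycles** — default 3, for the same reason.
* **Content mask** — a pixel participates when any channel deviates from
  the frame's modal 8-bit value by more than 2/255.  Contour exports
  have a non-zero colormapped background, so "content exists" must be
  judged against the background level, not against zero.
* **Frame rate** — the upstream workflow streams the images as a
  temporary video at a fixed FPS; playback rate has no mathematical
  effect and is accepted by the CLI only for configuration
  compatibility.

The recurrence is order-dependent (it is not a mean); the test suite
asserts this rather than claiming permutation invariance.  Channels are
processed independently, preserving color information.

## ROI discovery and deepstacking

Two group AFRCs are compared with a fixed-width, full-height window slid
along the first retention-time axis (default width W/16, stride = width,
a non-overlapping tiling; the window scans x because the first dimension
carries most of the chromatographic spread).  Each window pair is scored
by a similarity metric; the k windows with the lowest similarity
(default k = 5) are the regions of interest, stacked side by side in
ascending score order from every source image to form the "deepstacked"
dataset.  Ties break toward smaller x; overlapping candidates (stride <
width) are greedily suppressed.  The geometry is serialized as JSON so
inference can reuse exactly the training-time crop.

The default window score is the cosine similarity of features from a
fixed-seed random-convolution embedding (windows resized to 32×32, 24
random 3×3 filters, rectified, 4×4 average-pooled).  Random
convolutional features are a cheap, deterministic, training-free image
embedding; the extractor is a pluggable interface, so a pretrained CNN
can be substituted where its weights are available locally.  SSIM, PSNR,
average-hash Hamming similarity and a windowed Fréchet distance are
available as alternatives.

**Tie threshold.**  Whether a low-scoring window reflects genuine group
contrast is decided by split-half null calibration: each group's images
are split in half, an AFRC is built per half, and the two halves of the
same group are scanned against each other.  Dissimilarity seen there is
pure replicate noise (retention-time jitter, detector noise, bleed
variation).  The threshold is the worst within-group similarity widened
by a 1.5× safety factor on the dissimilarity scale.  The calibration is
conservative: the half-sized AFRCs are noisier than the full ones, so
weak markers may fall above the threshold (they are still ranked first
by the selector); in exchange, the amplitude-zero negative control
flags nothing.

## Adversarial contour synthesis

A DCGAN-style convolutional generator/discriminator pair (z ∈ R¹²⁸,
nearest-neighbour-upsample + conv generator stages from 4×4 to the
target resolution, stride-2 conv discriminator; square power-of-two
resolutions 64–512) expands small contour datasets.  Two objectives:

* **`logistic`** — the classic non-saturating min–max game,
  max_T E[log σ(T(x))] + E[log(1 − σ(T(G(z))))], generator loss
  −log σ(T(G(z))).
* **`qp`** (default) — the quadratic-potential objective: critic loss
  E[T(f) − T(r)] + E[(T(r) − T(f))² / (2λ·d(r, f))] with d the mean
  absolute pixel distance of a real/fake pair and λ = 10; generator loss
  E[T(r) − T(f)].  The quadratic term is a built-in Lipschitz penalty
  that keeps critic gradients bounded without weight clipping, which is
  what makes this family stable at 512×512.

The printed min–max formulation and the quadratic-potential family are
not the same objective; both are implemented and the choice is a flag,
so the discrepancy is surfaced rather than hidden.  Optimizers are Adam
(lr 2·10⁻⁴, β₁ 0.5, standard GAN practice).  Training records, at fixed
checkpoint intervals, the Fréchet distance (FID) between extractor
features of a synthesized batch and a real batch, and the qScore
(below); preview grids can be written per checkpoint.  Synthesis scales
the latent vector (z-scale ∈ [0, 2]) to produce intensity variants —
the image-level analogue of concentration variation — and the default
expansion is 10× the source count.  An augmentation bank (sharpen, blur,
noise, denoise, erode, dilate, distort, brightness, contrast,
edge-enhance) applies named filters in order, clipped to [0, 1],
deterministic per seed.

All networks run on a minimal in-package numpy layer toolkit
(`contourpro.nn`: im2col convolutions, manual backprop, Adam) — small,
dependency-free and fully deterministic given seeds.

## Sharpness, qScore and qScore ratio

The scalar sharpness statistic is the variance of the 3×3 Laplacian of
the BT.601 luma plane — the standard blur metric (0 for constant
images).  A sigmoid applied to a Laplacian yields an image, not a
number, so the batch-level score is defined on the log-ratio of mean
sharpness:

    qScore = σ( ln(S_synth / S_source) − ln(0.82/0.18) ),

calibrated so equal mean sharpness scores exactly 0.18 — the reference
point of the scale; blurrier synthesized batches score below 0.18,
sharper ones above.  The qScore ratio for super-resolution is
(S_hr − S_other)/S_hr: 0 at equal sharpness, 1 for a featureless
reconstruction, negative when the reconstruction is sharper than its
reference.  Both are directional by definition.

FID is ‖μ_a − μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_aΣ_b)^½), the cross term
computed as Tr((√Σ_a Σ_b √Σ_a)^½) via symmetric eigendecomposition with
negative eigenvalues clipped at zero.  PSNR is capped at 100 dB for
identical images (MSE = 0 is otherwise infinite).

## Super-resolution

A cascading residual network: feature stem, residual blocks whose
outputs are all concatenated and fused by 1×1 convolutions after every
block, and an upsample head (scale 2 or 4).  The head predicts a
residual added to a cubic-convolution (Catmull–Rom, a = −0.5) upsample
of the input, and the final convolution is zero-initialized, so the
untrained model reproduces bicubic interpolation exactly and training
only learns the high-frequency correction.  Loss is L1 (mean absolute
difference); the qScore ratio of reconstructions against their
references is tracked per epoch and trends toward zero.  Defaults:
scale 2, 3 blocks, 64 channels; the tests use 2 blocks × 16 channels.
Training data comes exclusively from the simulated contour-like pair
generator, mirroring how a contour-specific model is trained when real
high-resolution exports are scarce.  Super-resolution is an opt-in
pipeline stage: it improves synthesized image quality but is not
required by the classifier.

## Classification and inference

Datasets are split per group with a stratified shuffle, 85:15 by
default.  The default backbone is `small_cnn` — four stride-2
convolution blocks (12/24/48/48 channels), global average pooling and a
linear head — which trains deterministically from scratch.  `vgg16` and
`vgg19` are available as faithful convolutional stacks with a
global-pool head; the `inception_v3`, `resnet50` and `densenet` slots
are filled by compact five-block convolutional variants, documented as
such.  Pretrained weights, when used, must be a local `.npz` file;
nothing is downloaded.  One published resolution is quoted as 244×244;
since standard backbones use 224, the package simply accepts any square
input in [128, 512] and treats 244 as just another size rather than
silently correcting the figure.  Training is cross-entropy with Adam
(batch 8).  The classifier default learning rate is 10⁻³, chosen so the
four-block network converges within desk-scale epoch budgets; optional
augmentation applies random shear/skew/zoom to training batches only.
AUROC is computed by the rank (Mann–Whitney) statistic with half credit
for ties — identical to trapezoidal ROC integration — and is
macro-averaged one-vs-rest for more than two classes.

Inference assigns the argmax class when the maximum softmax probability
reaches the confidence threshold (0.85 default, boundary inclusive at
single-precision resolution); below-threshold samples are reported as
`unclassified` and retained in the report rather than dropped.  The
preprocessing of inference inputs (full frame vs. a specific deepstack
geometry, identified by a hash of its windows) must match the
classifier's training preprocessing; a mismatch raises an error.
Watermarked copies of the input images carry the verdict and confidence.
The HSV baseline — a flattened L1-normalized 8×8×8 joint HSV histogram —
is provided for comparisons against conventional feature-based
classifiers.

## Synthetic data generator

The generator emulates what the pipeline sees in real contour exports:
anisotropic Gaussian peaks on a fixed blue→green→yellow→red colormap
(contour palettes are vendor-specific; the pipeline does not depend on
the palette), uniform per-peak retention-time jitter (≤ 5% of the image
extent), additive Gaussian detector noise, and a column-bleed band along
the bottom H/8 rows with Gaussian vertical falloff (level 0.3 ≈ a
low-bleed run, 0.8 ≈ high bleed).  Two-group studies share a base peak
field (14 random peaks, amplitudes 0.35–0.9) while group B adds marker
peaks centered in disjoint scan windows, giving a known ground truth for
ROI recovery; marker amplitude 0 is the negative control.
Super-resolution pairs are fresh random peak fields downsampled
bicubically.

What the generator does **not** emulate: mass-spectral structure,
modulation-phase artifacts, peak tailing, co-elution, or vendor
rendering quirks.  Passing tests therefore demonstrate that the
algorithms behave as specified on images with contour-like statistics —
not that any clinical classification result transfers.

## Problem sizes used in the test suite

The automated checks run on one CPU in minutes, so they use reduced
problem sizes chosen as the package's own desk-scale defaults: ROI
recovery on 256×256 images, 15 per group, 3 planted markers; GAN
training at 64×64 for 200 iterations on 30 images; super-resolution at
64→128 with 24 simulated pairs for 10 epochs (2 blocks × 16 channels);
classifier training at 128×128 with 40 images per group for 20 epochs.
Stochastic training assertions are made on the median over three fixed
seeds.  Full-scale results (512×512 generative training, FID < 47,
clinical AUROC > 0.96) require GPU-scale computation and the original
clinical images, and are outside the scope of this package's test bed.

## Known limitations

* The tie threshold is conservative by construction (split-half AFRCs
  are noisier than full-group AFRCs); weak but real markers may not be
  flagged as significant even though the selector still ranks them
  first.
* The random-convolution embedding is not a semantic feature space; on
  real data a pretrained CNN extractor should be plugged in.
* The numpy networks are CPU-bound and intended for desk-scale
  experiments; the architecture parameters (channel widths, block
  counts) default small accordingly.
* Confidences are raw softmax probabilities; no calibration is applied.
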