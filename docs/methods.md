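# Methods

## The model

`styleharm` treats multi-site MR harmonization as unpaired multi-domain
image-to-image translation with explicit content–style disentanglement.
Given image sets {X_i} from N sites, every image x_i is decomposed into

* a **content code** c_i = E^C(x_i): a spatial feature map from a content
  encoder shared by all sites, intended to carry only site-invariant
  anatomy; and
* a **style code** s_i = E^S_i(x_i): a low-dimensional vector from a style
  encoder with one output head per site, carrying the site-specific
  appearance (intensity levels, contrast, sharpness).

A shared generator G(c, s) re-synthesizes an image from any
(content, style) pair, injecting the style through adaptive instance
normalization (AdaIN).  Styles can also be *sampled*: a mapping network
G^S_j turns a latent z ~ N(0, I) into a style of site j, giving the natural
intra-site appearance variation.  A per-site discriminator D_j scores
realism.

Training runs **content-style disentangled cycle translation**: a batch from
site i is translated forward into site j (x̃_j = G(c_i, s_j), with s_j from
the mapping network or from a real reference batch), then backward
(x̂_i = G(c̃_j, s_i) where c̃_j = E^C(x̃_j)), together with the
self-translation x̄_i = G(c_i, s_i).  Seven losses shape the solution
(all L1 norms are **means** over elements, so weights are canvas-size
independent):

| term | form | weight |
|---|---|---|
| adversarial | E log D_i(x_i) + E log(1 − D_j(x̃_j)) | 1 |
| content consistency | ‖E^C(x_i) − E^C(x̃_j)‖₁ | 10 |
| content alignment | KL(N(c_i, I)‖N(0, I)) = ½·mean(c²) | 0.01 |
| style diversity | ‖G(c_i, s_j) − G(c_i, s_j′)‖₁, z ≠ z′ | 1 (maximized) |
| style consistency | ‖s_j − E^S_j(x̃_j)‖₁ | 10 |
| cycle | ‖x_i − x̂_i‖₁ + 0.1·‖g(x_i) − g(x̂_i)‖₁ | 10 |
| identity | ‖x_i − x̄_i‖₁ | 10 |

Choices worth flagging:

* **Diversity sign.**  A diversity term *minimized* inside the total would
  collapse all sampled styles onto one appearance, the opposite of its
  stated purpose.  The generator therefore maximizes it (entered with a
  negative sign, magnitude clipped at `sd_ceiling`, default 0.5, for
  stability); `literal_diversity_sign=True` restores the minimized form.
* **Style consistency operands.**  The consistency is between the style
  *used for generation* (s_j) and the style re-extracted from the generated
  image — comparing the source style s_i against s̃_j would contradict
  disentanglement; `literal_style_consistency=True` selects that variant
  anyway for comparison experiments.
* **Content alignment and the perturbation.**  During training the content
  code fed to the generator is c_i = E^C(x_i) + η, η ~ N(0, I).  The
  alignment KL is computed on the clean code (the mean of the implied
  Gaussian); η is the sample of that Gaussian.  η is never applied to codes
  re-extracted from generated images, and never at inference.
* **GAN optimization.**  The discriminator ascends the printed two-term
  objective; the generator minimizes the non-saturating surrogate
  −E log D_j(x̃_j) (the literal minimax form has vanishing gradients early
  in training).  Scores are probabilities clamped to [1e-7, 1 − 1e-7]
  inside logs.
* **Image gradient g(·).**  Forward finite differences along both spatial
  axes, concatenated; the replicated edge contributes a zero difference.

## Networks and numerical backbone

No deep-learning framework is used: a compact reverse-mode autodiff engine
on numpy float32 (`_autodiff.py`) provides conv2d (im2col + BLAS matmul),
instance norm, nearest-neighbour upsampling, the pointwise ops and ADAM.
Gradients of every op are verified against central finite differences, and
whole-network gradients agree with float64 numerical differentiation to
~1e-7 relative error.

Default dimensions (all configurable via `ModelConfig`): canvas 64,
base width 16, content code 32 channels at canvas/2 resolution
(downsampling 2), d_s = 8, d_z = 16.  The content encoder is a conv stem,
one stride-2 conv and a residual block (instance-normalized); the generator
mirrors it with two AdaIN residual blocks, a sub-pixel (depth-to-space)
upsampling convolution, and a tanh output; style encoder and discriminator share a 4-layer strided conv
trunk shape with per-site linear heads; the mapping network is a 2-layer
MLP with per-site heads.  Three deliberate initialization choices: AdaIN
style projections start at 0.1× He scale, so the early model behaves like a
style-agnostic autoencoder and style modulation grows in through the
adversarial and style-consistency gradients; the sub-pixel convolution uses
ICNR initialization (all four phases share one filter), making it exactly
nearest-neighbour upsampling at step 0 and free of checkerboard artifacts —
plain sub-pixel initialization measurably degraded FID; everything else is
He-normal, seeded, bit-reproducible.

A downsampling of 2 (not more) keeps the content code at 32×32: desk-scale
experiments with a 16×16 code produced visibly blurred re-synthesis, which
hurt segmentation-consistency and identity-translation fidelity.

## Training

Each step samples an ordered site pair (i, j) uniformly over all N(N−1)
pairs, draws a batch per site, updates the discriminator on (real x_i at
branch i, fake x̃_j at branch j), then updates all generator-side modules
with the discriminator frozen.  Style sourcing alternates stochastically
between the latent path and the reference path (`style_source_mix`, default
0.5); the diversity term exists only on the latent path (a single reference
image cannot supply two styles), and reference-path steps log it as 0.

A discriminator-at-chance stopping rule is not operational in practice;
training runs a fixed `total_steps` and logs
discriminator calibration instead.  All randomness flows through one seeded
PCG64 generator stored in `TrainState`; checkpoints save parameters, ADAM
moments, the rng state and the loss history, so restore-and-continue is
bitwise identical to an uninterrupted run (at a fixed BLAS thread count).

The package-wide optimizer default is ADAM at learning rate 1e-4 (standard
β).  The desk-scale study (`experiments.train_study`) uses 3e-4: with only
~1500 updates on a small model, 1e-4 is measurably underfit (the
reconstruction losses are still falling steeply when the budget ends),
while raising the rate further added nothing.  This is a scale adaptation
for the synthetic desk-scale setting, not a statement about full-scale
training.  Batch size defaults to 4; with the engine's
batched trunk passes and the pre-upsample sub-pixel convolution, a
1500-step run fits in roughly twelve minutes on one CPU.

## The synthetic multi-site data

Real multi-site MRI with traveling-phantom ground truth is access
restricted, so `synthetic_sites` emulates the structure the method assumes:

* **Content** — a nested-ellipse head phantom (CSF-like outer ring,
  GM-like shell, WM-like core, a small CSF-like ventricle), warped by a
  smooth random deformation field (Gaussian-smoothed noise, RMS amplitude
  4% of the canvas).  Classes 0–3, all present in every anatomy.
* **Style** — per site: tissue-class mean intensities (drawn from disjoint
  per-class ranges, site vectors rejection-sampled to stay ≥ 0.12 apart in
  max-norm so sites are identifiable from appearance alone), a contrast
  exponent γ ∈ [0.75, 1.3] (rendered value = mean^γ), a multiplicative
  bias field (smoothed noise, amplitude 2–8%, correlation length 12–24 px),
  Gaussian blur (FWHM 1–2.5 px), additive noise (σ 0.01–0.03) and
  intra-site jitter (2% relative SD on class means and γ).  Jitter gives
  the style generator a real intra-site distribution to learn; its
  magnitude is a free choice, not a claim about any real study.
* **Pairing** — training sets use site-disjoint anatomy seeds (unpaired,
  as in real studies); the paired test set renders each held-out anatomy
  under *all* site styles (synthetic traveling phantoms) with ground-truth
  masks retained.

What this does not emulate: real brain geometry, 3-D through-plane
structure (2-D phantoms are replicated into the three 2.5D channels),
scanner-specific artifact families (ghosting, motion, wrap-around), and
realistic tissue heterogeneity.  Passing the synthetic study shows the
machinery disentangles and transfers the *kind* of appearance variation it
models — global intensity/contrast/smoothness differences — not that it
harmonizes any particular real dataset.

## Evaluation

* **Paired fidelity**: MAE, PSNR (peak 2 for [−1,1] data, capped at 100 dB
  when MSE = 0) and a multi-scale structural similarity score (weighted
  geometric mean of per-scale SSIM over dyadic scales; the scale count
  adapts so the 11-px Gaussian window always fits; negative per-scale
  values clip to 0).
* **Segmentation consistency**: an internal phantom segmenter — background
  as the lowest of four deterministic quantile-initialized 1-D k-means
  intensity clusters restricted to the largest connected component, then
  3-means over foreground intensities, labels in ascending mean order.
  Scale- and shift-invariant by construction.  Dice coefficient with the
  empty/empty convention DSC = 1.
* **Distributional distance**: FID on Gaussian fits of feature embeddings
  (matrix square root via symmetric eigendecomposition with negative
  eigenvalues clipped at 0) and unbiased KID (degree-3 polynomial-kernel
  MMD², full sets at desk scale).  The default embedding is a fixed,
  seeded, *untrained* 3-layer convolutional feature extractor with global
  mean+SD pooling — download-free and deterministic; any callable
  `(N, H, W) -> (N, d)` (e.g. a pretrained network) can be substituted.
  Absolute FID/KID values under this embedding are not comparable to
  values from pretrained embeddings; the harness only uses relative comparisons
  (harmonized vs unharmonized against the same target set).
* **Sharpness**: edge transition width ≈ 0.8·(local swing)/(max slope)
  at the steepest edges of the center row/column profiles — exactly 0.8 px
  for an ideal step, proportional to blur scale, robust to the short
  plateaus between neighbouring tissue transitions.

## Inference modes

Site mode draws one latent style per output volume (shared across slices to
avoid through-volume appearance flicker); reference mode extracts one style
from the reference's central 2.5D slice; identity mode uses each slice's
own extracted style; interpolation decodes (1−β)s_A + βs_B along a β grid.
Harmonized slices are denormalized with the *source* slice's recorded
(min, max) — generated images have no native intensity scale, and the
source scale keeps volumes comparable before/after harmonization.

## Degenerate inputs and numerical conventions

Constant slice channels normalize to zeros and are flagged (and restored on
inversion).  Padding centers the image with the extra pixel bottom/right on
odd differences.  Reassembly requires a consistent center-index grid and
refuses duplicates or gaps.  The 2.5D window stride is 1 with edge
replication for training; at inference each window contributes only its
center channel (no overlap averaging).  Whether channel normalization is
per-slice or per-volume is ambiguous in the field; per-slice is the default
here and a per-volume option exists in `volume_io`.

## Desk-scale problem sizes

The packaged study trains 3 synthetic sites at 64×64 with 50 training
anatomies per site and 10 paired test anatomies for 1500 steps (batch 4)
— a configuration chosen to run end-to-end in minutes on a single CPU.
The same harness scales to larger canvases and deeper models through
`ModelConfig`/`TrainConfig`.

## Known limitations

* The numpy engine is single-device and eager; it is meant for desk-scale
  models, not 256×256 production training.
* 2-D phantoms exercise the 2.5D plumbing only through replicated
  channels; volumetric smoothness across slices is tested structurally
  (reassembly contracts), not learned from data.
* The untrained FID/KID embedding supports relative statements only.
* Training length at desk scale leaves the GAN far from its asymptotic
  regime; harmonized images are quantitatively better than unharmonized
  ones under every metric tracked, but not photorealistic replicas of the
  target site.
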