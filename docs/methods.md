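# Methods

## Problem and model

Single-cell microscopy collections for hematological cytology are heavily
imbalanced: common cell families (neutrophils, lymphocytes) contribute
thousands of images while clinically important rare types (monoblasts,
promyelocytes, smudge cells) contribute tens. `cytogan` implements a
class-conditional generative model whose purpose is to synthesize images
of the rare classes so that a downstream cell-type classifier can be
trained on a balanced dataset, together with the preparation and
evaluation machinery around it.

The model is a hybrid of two standard GAN designs:

* **Wasserstein critic with gradient penalty.** The critic `D` outputs an
  unbounded realness score and is trained to minimize

      L_critic = E[D(G(z,c))] − E[D(x)] + σ · E[(‖∇_x̂ D(x̂)‖₂ − 1)²]

  where `x̂ = ε·x + (1−ε)·G(z,c)` with per-sample `ε ~ U[0,1]`, and the
  penalty coefficient is σ = 10. The generator minimizes `−E[D(G(z,c))]`.
  The penalty is applied to the source head only: it enforces the
  1-Lipschitz condition on the Wasserstein score, not on the classifier.

* **Auxiliary classifier.** The critic carries a second head producing
  class logits. It never receives label inputs (unlike a conditional
  discriminator); instead it is trained by cross-entropy to recover the
  class of real images and the conditioning class of generated images:

      C_L = E[log P(C=c | x_real)] + E[log P(C=c | x_synth)]

  The critic adds `−λ_cls · C_L` to its objective and the generator adds
  `−λ_cls · E[log P(C=c | G(z,c))]`, with λ_cls = 1 by default (the
  weight is exposed because the literature does not fix it). Setting
  λ_cls = 0 recovers plain WGAN-GP; setting σ = 0 and using the
  cross-entropy source surrogate recovers the AC-GAN loss family — both
  ablations are reachable from configuration.

  A probabilistic "source log-likelihood" is also reported for
  monitoring, obtained by mapping the unbounded scores through a
  logistic function. It is never optimized: for a Wasserstein critic the
  adversarial source term *is* the Wasserstein objective.

### Architecture

The generator projects a 128-d (configurable) standard-normal noise
vector and a learned class embedding to two 4×4 feature maps, concatenates
them channel-wise, applies `log2(image_size/4)` residual upsampling blocks
(pre-activation, batch normalization, nearest-neighbour upsample, two 3×3
convolutions, 1×1 skip projection), then batch-norm → ReLU → 3×3 conv →
tanh, so outputs live in [−1, 1].

The critic mirrors this with residual downsampling blocks (average-pool
downsampling) but uses **layer** normalization: the gradient penalty is a
per-sample statement and batch statistics would couple samples, which
invalidates it. Features are globally average-pooled and fed to two
linear heads (source score, class logits).

Channel widths double per halving of resolution from `base_channels`,
capped at 8×. Feature maps are channels-last (NHWC).

### Numerical engine

All networks run on a compact reverse-mode automatic-differentiation
engine over NumPy arrays (`cytogan.engine`). Every backward rule is
itself composed of engine primitives, so second-order gradients — which
the optimizer needs to differentiate the gradient penalty with respect
to the critic weights — come out of the same machinery
(`grad(..., create_graph=True)`). Convolutions are im2col + BLAS matmul
with a cached sparse scatter matrix for the adjoint. The engine keeps
everything in float32 during training; gradient checks in the test suite
run in float64 against central finite differences (first order ~1e-9
relative, second order ~1e-4).

The engine is sized for desk-scale experiments on a single CPU; it is
not a GPU framework and does not try to be one.

## Dataset preparation

Manifests are CSV tables (`path,label,source,split`). Preparation follows
standard multi-source cytology curation:

* **Cell-family merging** is data, not code: a taxonomy maps source
  labels to merged families. The default collapses lymphocyte
  (typical/atypical), neutrophil (band/segmented), promyelocyte
  (bilobed), and the immature-granulocyte precursors
  (myelocyte/metamyelocyte); everything else passes through. 19 input
  labels become 12 families.
* **Deduplication** collapses byte-identical files (content hash) and
  drops records on an explicit exclusion list. Expert judgments that
  remove individual images (e.g., one mislabeled neutrophil in the
  reference tables) are modeled as exclusions rather than hard-coded
  count edits. Near-duplicate perception is out of scope.
* **Stain normalization** is Reinhard color transfer: per-channel
  mean/std matching in LAB space against a reference image, clipped back
  to gamut. The moment transfer itself is exact; the RGB round trip can
  clip out-of-gamut pixels.
* **Stratified splitting** assigns per class floor(30%) to test, then
  floor(20% of the remainder) to validation, remainder to train —
  deterministic given the seed. Classes with fewer than three records
  are rejected by name.
* **Balancing deficits** are `target − count` per class, floored at 0,
  with `target = "max"` meaning the largest class.

## Toy-cell fixture

Real cytology collections cannot ship with the package, so training,
metrics and classifiers are exercised on a generated fixture: each image
is one elliptical "nucleus" whose hue identifies the class (hues ≥ 60°
apart), with class-specific radius distribution and texture frequency, on
a tinted background with band-limited texture and pixel noise. One class
is deliberately a small minority (default counts 200/200/200/10) so the
balancing workflow has something to balance.

Because class identity is carried by hue, a *measurement oracle* —
circular mean hue of saturated pixels — can score whether
class-conditional samples match their class without any learned model.
What fixtures do **not** emulate: morphology beyond an ellipse, staining
variation, chromatin texture, inter-class ambiguity. Passing tests show
the machinery learns and evaluates class-conditional structure; they say
nothing about visual fidelity on real smears.

## Study conditions (problem sizes)

Published experiments at full scale use 128×128 patches, batch 64,
50 epochs, learning rate 0.001, σ = 10. This package keeps the learning
rate, σ, optimizer (Adam, betas 0.5/0.9) and the alternating update
scheme (n_critic critic steps per generator step), but its bundled smoke
experiments run at desk scale, chosen once as the package's reference
conditions:

* fixture: 4 classes, 200/200/200/10 images, 32 px
* GAN: noise 32, base_channels 8, image 32 px
* training: batch 16, n_critic 2, 6 epochs (~21 iterations each,
  ~126 generator updates)

Iterations per epoch are derived from the data size (⌊n/batch⌋), never
hard-coded. Under these conditions the conditional hue error of generated
samples falls from ~84° (epoch 1, i.e., chance-level ~90°) to ~25°, and
the auxiliary classifier reaches ~0.9 accuracy on real batches.

## Evaluation suite

* **Inception score**: exp of mean KL(p(y|x) ‖ p(y)), computed on 10
  contiguous chunks, reported mean ± sd; bounded in [1, K].
* **FID**: ‖μ_R − μ_S‖² + Tr(Σ_R + Σ_S − 2(Σ_R Σ_S)^{1/2}) with the
  principal matrix square root; negative eigenvalue noise clipped.
  Covariances use the maximum-likelihood convention (divide by N) —
  stated explicitly because the literature varies.
* **Feature backbones are pluggable**: a "pixel" backbone (downsampled
  pixels, no pretrained weights — used in tests) and an "aux-critic"
  backbone (the trained critic's pooled features; its class head supplies
  p(y|x) for the inception score). Absolute values from pretrained
  Inception-style backbones are not reproducible here and are not
  claimed; reports record which backbone produced each number.
* **Paired metrics** (l1, l2, MSE/PSNR, SSIM, LPIPS-style perceptual
  distance) require pairs, but a GAN is unpaired; the pairing strategy is
  explicit and recorded: nearest real neighbour within class by MSE
  (default) or random within class, both seeded. PSNR of identical
  images is +inf (a cap is available for CSV export). SSIM uses
  K1=0.01, K2=0.03, 7×7 uniform window, unbiased local covariances,
  C3=C2/2, per-channel averaging.
* **Classification summaries**: macro precision/recall/F1 and per-class
  one-vs-rest accuracy/sensitivity/specificity from a confusion matrix —
  one code path shared by the auxiliary classifier and downstream
  classifiers.

## Downstream comparison

Six equally sized, class-stratified training conditions are built:
original, synthetic, three named augmentation recipes
(augmentation-1 = scaling+rotation+color-jitter, augmentation-2 =
translation+contrast+scaling, augmentation-3 = saturation+scaling+
rotation; parameter ranges: scale 0.8–1.2, rotation ±30°, translation
±10%, contrast/saturation ±20%, hue ±10° — the recipes name their ops,
the magnitudes are package defaults), and original+synthetic. The
combined condition samples from the union of the original pool and the
(balanced) synthetic pool, so its class mix moves toward balance at
fixed total size. All conditions share one held-out test split never
used for training or synthesis conditioning.

The classifier is a small 3-block CNN with a linear head (registered
under `small-cnn`; the registry accepts user architectures). Large
pretrained backbones are deliberately not bundled: the comparison is
about the *relative* effect of balanced synthetic data, which the small
classifier exposes at desk scale.

## Numerical choices and edge cases

* Gradient penalty: per-sample gradient norms are computed without an
  epsilon inside the square root, so the unit-gradient identity and the
  constant-critic value (exactly σ) hold exactly; a critic whose output
  is constant in its input yields the analytic value σ directly.
* NaN anywhere in a recorded loss aborts training with the term name and
  iteration.
* Fake-batch labels are drawn from the empirical class frequencies of
  the training split (uniform sampling is a flag).
* Checkpoints are single `.npz` archives holding both networks'
  parameters and buffers, optimizer state, configs and epoch, with a
  version field.
* Determinism: a single integer seed fixes fixture rendering, splits,
  weight init, batch order, noise, ε draws and synthesis; identical
  seeds reproduce identical histories on the same platform (bit-exact
  results across BLAS builds are not guaranteed).

## Known limitations

* No GPU path; wall-clock scale is hundreds of generator updates, not
  the tens of thousands of full-scale GAN training.
* Pixel/critic backbones give relative, not literature-comparable,
  FID/IS values.
* Byte-level deduplication only.
* The fixture's class signal (color) is far easier than real
  cytomorphology; downstream gains measured on it are a mechanism check,
  not a clinical claim.
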