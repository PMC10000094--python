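# Methods

`trapslim` implements a design loop for lightweight camera-trap wildlife
classifiers: mitigate background shortcut learning with mixed data
augmentation, compress the trained network by genetic channel-pruning
search with adaptive batch-normalization, and recover accuracy with
knowledge-distillation fine-tuning. This note records the models, the
parameters that matter, the synthetic study conditions, and the numerical
and design choices behind them.

## The shortcut-learning problem and the synthetic scenes

Camera traps are fixed, so all images from one site share a near-constant
background. When a species is photographed mostly at its own sites, the
background alone predicts the label in training data; a classifier that
exploits this shortcut collapses when species and sites are paired
differently at test time.

The `synthdata` module manufactures this structure explicitly:

- **Sites.** Each site has a base hue (evenly spaced on the hue circle), an
  oriented sinusoidal texture with a site-specific frequency, per-pixel
  Gaussian noise (sd 8) and per-frame exposure jitter (sd 6). The signature
  is strong enough that a logistic probe on 8x8 pooled pixels identifies
  species from the background almost perfectly on a confounded training
  split (verified in the test suite).
- **Species.** Each species is a radial silhouette
  `r(theta) = r0 (1 + 0.30 cos(k theta + phase))` with lobe count
  `k = label + 2`, so species are separable by shape alone; the fill colour
  is neutral grey pulled toward a species hue by `foreground_contrast`.
  At contrast 0 the animal is invisible; the default 0.35 keeps the animal
  a visibly weaker cue than the background, which is what makes the
  shortcut attractive to a classifier.
- **Confound.** A training image of species `s` comes from `home_site(s)`
  with probability `confound_strength` (default 1.0, the fully confounded
  regime); test images pair species and sites uniformly. The default split
  of 28 train / 12 test instances per class keeps the conventional 7:3
  ratio.

What the generator deliberately does *not* model: photographic realism,
multiple animals per frame, occlusion by vegetation, day/night cycles, or
class imbalance. Passing tests therefore demonstrate that the algorithms
behave as designed under a controlled confound — not that they reach any
particular accuracy on real camera-trap imagery.

## Mixed data augmentation

- **Image synthesis (IS).** An instance cutout is rotated uniformly in
  [0°, 360°), rescaled uniformly in [0.6, 1.4], and pasted at a uniform
  in-bounds position on a random background frame. Order of operations:
  rotate about the cutout centre, then scale, then place; patches are
  resampled bilinearly, masks nearest-neighbour, and the mask is re-rasterized
  after the affine map so the bounding box stays tight. The toolkit takes
  instance masks as *inputs* (the generator provides exact ones); weakly
  supervised segmentation is out of scope.
- **Regional background suppression (RBS).** A rectangle with area fraction
  uniform in [0.05, 0.25] and aspect ratio log-uniform in [1/3, 3] is
  rejection-sampled (up to 100 tries) until disjoint from the bounding box,
  then filled with raw pixel value 0 (before normalization). Foreground
  pixels are untouched by construction; if no disjoint rectangle exists the
  image is passed through unchanged with a warning. Plain cutout
  (rectangles anywhere, foreground included) is provided as the standard
  contrast.
- **Mixing.** `build_augmented_set` appends `is_fraction * N` synthesized and
  `rbs_fraction * N` suppressed records (defaults 0.5 each, doubling the
  set), with additions following the original class balance.

## The classifier and training

Desk-scale experiments use a small conv-BN-ReLU network (default stages
16/32/64, one stride-2 block per stage, global average pooling, linear
head) implemented on the package's own numpy engine, which provides exact
reverse-mode gradients, per-layer access to activations, and directly
sliceable weight tensors. The full-size ResNet50 teacher exists as an
analytic architecture descriptor for cost accounting; training it is
GPU-scale work outside this package's scope.

Training is SGD with momentum 0.9 and cosine learning-rate decay, early
stopping on validation accuracy. The published full-scale settings
(lr 1e-4, batch 64, patience 50) are kept as `published_train_config`; the desk
preset uses lr 0.05, batch 16, and 45 epochs — the epoch budget was chosen
so that training on the doubled (augmented) desk dataset converges, and the
best-validation weights are restored at the end.

## Cost accounting

Parameters: conv `cout*K^2*cin` (+`cout` if biased), fc `cin*cout + cout`,
BN `2*cout`. MACs: conv `H*W*cout*(K^2*cin + 1)` — the per-output-position
accounting with the accumulator slot charged for every conv — plus one op
per output element for BN and ReLU, `K^2` ops per spatially pooled output
element, one op per input element of the global pool, and the fc product.
Under this convention the 6-class 448x448 ResNet50 table costs exactly
23,520,326 parameters and 16.48 G MACs. A doubled `flops = 2*macs` field is
exposed for the multiply+add reading. All arithmetic is integer-exact and
additive over layers.

## Pruning search

A genome assigns each prune group a keep-ratio from the grid
{0.1, ..., 1.0}; pruned widths are `max(1, round(ratio * c))` (round half
up, floor of one channel so every layer survives). Residually coupled
layers share a group so pruned tensors stay shape-compatible. Candidates
are rejection-sampled until their MAC ratio lies in the compression band
(default 50 ± 5%).

Evaluation of a candidate: slice the teacher keeping the channels with the
largest filter L1 norms (the standard structured-pruning heuristic; scores
are summed across a group's convs), freeze all weights, then replace every
BN layer's inference statistics with the average over `recal_batches`
calibration mini-batches of the batch mean and *unbiased* (N−1) variance —
adaptive BN. Variances are floored at 1e-5 to guard degenerate batches.
Validation accuracy of the recalibrated sub-network, with no gradient
steps, is the quality signal.

Fitness follows the printed formula `f_j = n_j * p_j / p_0` (validation
accuracy times parameter ratio). As written it rewards *larger*
sub-networks inside the band; because the prose goal is compression with
accuracy, the alternative reading `n_j / (p_j / p_0)` is implemented behind
`fitness_form='accuracy_per_size'`. The literal form is the default so the
published formula is what runs unless the user opts out.

GA internals the source method leaves open were fixed as: uniform per-gene
crossover of two distinct uniformly drawn parents, per-gene mutation
probability 0.1 (resample from the grid), parents carried into the next
evaluated pool (elitism, which makes best fitness non-decreasing), and
termination when the pool's total fitness changes by less than 1e-3
(relative) for 3 consecutive generations, capped at 30. The published
preset keeps 20 parents and breeds 100 offspring; the desk preset uses
12/36 with 4 calibration batches. The random-sampling baseline evaluates
the same number of band-constrained candidates with the identical
adaptive-BN protocol, so the comparison isolates the evolutionary
mechanism.

## Distillation

Fine-tuning minimizes `CE(student, labels) + lambda * KD` with the teacher
frozen; `lambda` defaults to 1. KD variants: `mse` — mean squared
difference of softmax output distributions (the primary method; a
logit-space variant is available behind `on_logits` for sensitivity
checks); `soft_kl` — `T^2 * KL(teacher || student)` on temperature-softened
distributions (T defaults to 1; no temperature is prescribed by the source
method); `hard_kl` — cross-entropy against the teacher's argmax
pseudo-labels. Probabilities are clipped at 1e-12 inside logarithms.

## Metrics

`acc_cls` is the micro average `sum_i TP_i / sum_i (TP_i + FP_i)`, which
reduces to total-correct over total. Grad-CAM weights each final-stage
feature map by the spatial mean of the class-logit gradient, applies ReLU
to the weighted sum, and upsamples bilinearly; the target layer is the last
convolutional stage (configurable). FRoH is the heat inside the labelled
box over total heat; it is invariant to positive rescaling, so heatmaps
are deliberately not normalized. Dataset FRoH targets the true class by
default (predicted-class mode is available); zero-heat records score 0 and
are flagged.

## Study conditions and problem sizes

- **Shortcut study** (seeds 1–3): 4 species at 4 fully confounded sites,
  96x96 scenes, contrast 0.35, 28/12 records per class, desk training,
  half-and-half IS/RBS mix. Expected shape: baseline reaches ~1.0 train
  accuracy but near-chance decorrelated-test accuracy; mixed augmentation
  restores test accuracy by tens of points and raises FRoH.
- **Compression study** (seeds 1–3): an *unconfounded* 6-species scene at
  48x48 (compression quality is orthogonal to the shortcut, so the teacher
  should generalize), a 6-block teacher (stages 12/24/48, two blocks each)
  whose six independent prune groups give a genome space of about 10^6 —
  far larger than the 288-evaluation search budget, which is what gives an
  optimizer room to beat random sampling — searched at 50 ± 5% with the
  12/36 preset for up to 8 generations.
- **Distillation study** (seeds 1–3): the best genetic-search student per
  seed, fine-tuned 20 epochs per KD variant against its teacher.

## Known limitations

- The numpy engine is single-threaded-CPU oriented; it is not intended for
  448x448 training, and no GPU path exists.
- Identity-skip residuals only (no projection shortcuts); no grouped or
  depthwise convolutions, so the descriptor language covers plain CNN and
  bottleneck-residual tables, not arbitrary graphs.
- Exact reproducibility is per-platform: results are deterministic under a
  seed on a fixed BLAS, but bitwise identity across BLAS builds is not
  guaranteed.
- The stochastic study claims are median-over-seeds orderings at desk
  scale; they mirror the qualitative behaviour of the full-scale method,
  not its published accuracy figures.
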