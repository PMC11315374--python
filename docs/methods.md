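# Methods

## The model

Plant-disease symptoms split broadly into two perceptual regimes: lightly
infested leaves show a few spatially confined, textured lesions, while
heavily infested leaves show image-wide discoloration. A convolutional
encoder (sliding-window receptive fields) perceives the first regime well;
a full-field encoder (attention-style global mixing) perceives the second.
The network implemented here runs both encoders in parallel and fuses them.

Per image, each encoder emits a three-scale feature pyramid (B1/B2/B3 at
strides 8/16/32 with increasing channel widths). The pipeline is then:

1. **Adaptive feature fusion (AFF)**, per scale. The local map `X_L` and
   global map `X_G` (identical shape `C×H×W`) are concatenated on the
   channel axis; a 3×3 convolution (stride 1, padding 1, bias) maps the
   `2C` channels to 2; a softmax across those two channels at each spatial
   position yields complementary gates `W_L + W_G = 1`. The fused map is
   the pointwise convex combination `A = X_L ⊙ W_L + X_G ⊙ W_G`, so fusion
   can prefer local evidence at some positions and global evidence at
   others.
2. **Projection** of each fused scale to a common width `D` by a 1×1
   convolution, restoring the shared-channel precondition of cross-scale
   fusion (the three scales natively carry different widths).
3. **Hierarchical mixed-scale units (HMU)**, one per input of each fusion
   pair: channels are expanded by a convolution, split into `G` groups, and
   processed iteratively — each group is convolved into three equal parts;
   the first part is concatenated into the next group (feature
   interaction); the second parts jointly produce modulation weights
   `α = σ(conv_1×1(·))`; the third parts, scaled by `α`, are projected back
   to the input width, batch-normalised and added residually:
   `H = A(X) + N(T(α ⊙ concat g₃))`.
4. **HMU-guided feature fusion (HMUFF)**, per scale pair. The two refined
   maps are flattened over space (`C×S₁`, `C×S₂`, row-major) and compared
   through the negative Gram matrix `−E = −FH₁ᵀFH₂`. Softmax-normalising
   `−E` row-wise gives a stochastic matrix whose row `s₁` is a weighted
   average over the other map's positions; multiplying it onto `FH₂ᵀ` and
   reshaping yields the transfer `F₁₂` (and column-wise, transposed, the
   transfer `F₂₁`). Both are added residually: `X₁₂ = X₁ + F₁₂`,
   `X₂₁ = X₂ + F₂₁`. Because the similarity enters negated, positions
   receive relatively more of what they resemble *least* — the
   "differentiated" information the other scale carries.
5. **Deep supervision.** Each branch is globally average-pooled into its
   own `D → K` linear head. Training minimises the unweighted sum of
   per-branch cross-entropies; inference averages the per-branch logits,
   applies softmax, and takes the argmax (ties to the lowest class index).

## Design choices where the design was open

- **Softmax axes.** The AFF softmax runs across the 2 output channels,
  independently per spatial position — the only reading under which the
  gates act as complementary spatial weights. The difference matrix is
  normalised over `S₂` (rows) for the transfer onto map 1 and over `S₁`
  (columns, then transposed) for the transfer onto map 2; the column form
  is forced by dimensional consistency (`S₁×S₂` cannot left-multiply
  `C×S₁`), and makes each fused position a convex average of the other
  map's positions in both directions. A temperature on `−E` is exposed and
  defaults to 1.
- **HMU structure.** Defaults: `G = 4` groups, expansion ×2 via 3×3
  convolution, group interaction by concatenation + 3×3 convolution to
  three equal parts, `α = sigmoid` of a 1×1 convolution, `N` = batch
  normalisation, `T` = 3×3 convolution, residual activation `A` =
  identity (a ReLU variant is configurable). The expanded width must
  divide into `G` groups of three equal parts; when not pinned explicitly
  it is rounded up to the smallest multiple of `3G` at or above
  `expansion·C`, so any channel count is usable (e.g. `C=16` expands to 36,
  not 32).
- **Fusion topology.** All three unordered scale pairs by default; each
  branch's incoming fusion terms are summed before its single residual
  add. One HMUFF module (with its own two HMUs) per pair.
- **Ablation switches.** `use_aff=False` replaces AFF by the elementwise
  mean of the two branch maps; `use_hmuff=False` skips cross-scale fusion;
  `active_branches` masks scales; `encoder_mode` builds single-encoder
  ("local"/"global") classifiers for dual-vs-single comparisons.
- **Numerics.** Softmax is always max-subtracted; sigmoid is evaluated in
  its overflow-free form. The autodiff engine follows the input dtype:
  training runs float32, reference comparisons run float64.

## The autodiff engine

No deep-learning framework is used: `lgnet.tensor` is a compact
reverse-mode autodiff engine over numpy arrays, and `lgnet.nn` provides
the layer set the network needs (conv2d via im2col with an explicit
col2im backward, batch normalisation with running statistics, linear
layers, SGD with momentum and L2 weight decay, parameter-group support).
Every differentiable operation is validated against central finite
differences in the test suite, and conv2d additionally against
scipy's dense correlation and a quadruple-loop reference.

## Encoders

The shipped encoders are deliberately small (the full model is ~111k
parameters at widths 16/32/64) so everything trains in minutes on one CPU
core; `BranchSpec` abstracts the taps (channels/strides per scale) so
larger encoders can stand behind the same contract. Both trunks are
patch-merging stacks (4×4 stride-4 stem, then 2×2 stride-2 stages with
1×1 mixing convolutions), which gives an exactly tile-bounded receptive
field: a B3 cell of the *local* encoder sees precisely its 32×32 input
tile. The *global* encoder additionally adds a transformed
global-average-context vector to every position after each stage, so any
pixel can influence every output position — the property the receptive-
field probe in the tests verifies by finite differences.

## Training protocol

Parameters split into two labelled groups — backbone encoders vs.
everything new (AFF, projections, HMUFFs, heads) — each with its own
learning rate under one SGD optimiser (momentum 0.9, weight decay 5e-6,
batch 32). The default rates (2e-5 backbone, 2e-4 new) correspond to the
fine-tuning regime in which the encoders start from pretrained weights.
The synthetic benchmark trains from scratch, where those rates are far too
small; `toy_train_config()` therefore sets both groups to 0.02 (chosen
once between 0.05 and 0.02 on the seed-0 toy run: 0.02 converged faster
and more stably) and 30 epochs. Augmentation (training split only):
uniform rotation in ±30° and horizontal flips with probability 0.5, both
drawn from the run seed. Input images are scaled to [0,1] and normalised
by per-channel training-split statistics, which are stored in the
checkpoint. Per epoch the validation split is scored (accuracy, macro
precision/recall/F1, per-branch head accuracy); the best-validation-
accuracy state is retained. The learning-rate schedule is constant by
default with a cosine option. Runs are exactly reproducible on one
device: the same seed reproduces epoch losses bit for bit.

## Metrics

`confusion` tallies one-vs-rest TP/FP/FN/TN per class; `scores` computes
per-class accuracy, precision, recall and F1 from those counts and
macro-averages precision/recall/F1 (micro and support-weighted variants
behind a flag; the averaging rule is recorded in the result). Overall
accuracy is the fraction of exactly correct predictions. Classes with no
predicted positives score precision 0 and are flagged.

## The synthetic benchmark

`generate_synthetic` renders textured green elliptic leaves on a dark
backdrop, 64×64 by default (any stride-32-divisible size works). Classes
come in two modes:

- **local** ("blotch": 1–3 compact dark-rimmed, bright-centred spots;
  "speckle": a swarm of ~2.4 px dots). The two families share the lesion
  colour, the per-pixel shade distribution (70% dark tone, 30% bright
  tone) and the total lesion area (uniform 90–190 px²), with containment
  and overlap handling so effective areas match; their colour histograms
  are therefore nearly indistinguishable and only spatial texture
  separates them.
- **global** ("yellowing" vs. "browning"): a low-frequency mottle field
  thresholded to cover 45–70% of the leaf is recoloured toward a
  class-specific hue, so image-level colour statistics suffice.

The generator's self-test fits a logistic model on per-channel 8-bin
colour histograms (standardised features): the global pair is separable
(accuracy ≈ 1.0), the local pair is not (≈ 0.5–0.6, threshold < 0.7 on a
held-out 25%). Defaults: 4 classes alternating local/global, 250
images/class, all randomness from one seed; regeneration is bit-identical
and written PNG trees are byte-identical.

What the benchmark does *not* emulate: real lesion biology and shape
diversity, illumination and background clutter, camera noise, class
imbalance, and fine-grained severity grading. Passing the toy experiments
shows the architecture, gradients, and training loop behave as designed —
not that the model reaches field-grade accuracy on real imagery.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks use 20 seeded instances per block at `C ≤ 8`,
spatial sides ≤ 4. The toy training experiment uses 4 classes × 250
images (800 train / 200 validation), widths 16/32/64, up to 30 epochs.
The dual-vs-single ablation uses 4 classes × 125 images (400/100), 12
epochs, median over seeds 0–2; its margin is asserted at ≥ −2 percentage
points to absorb seed noise. These sizes are the package's chosen
benchmark conditions and are what `scripts/acceptance.py` re-runs.

## Known limitations

- The engine is single-threaded numpy; it is sized for the shipped tiny
  models, not for 224×224 ImageNet-scale encoders.
- No pretrained encoder weights are shipped or downloaded; `pretrained`
  in `BranchSpec` is interface surface for larger drop-in encoders.
- The difference-matrix memory cost is `S₁×S₂` per pair; at large spatial
  sizes a chunked or sparsified variant would be needed.
- Checkpoints store the full config and vocabulary and are versioned, but
  no cross-version migration is implemented.
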