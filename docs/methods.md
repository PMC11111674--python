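# Methods

## The model

`ldinet` implements a single-branch multi-label classifier for leaf images.
The target for an image is a multi-hot vector over the concatenated label
vocabulary plants ‖ diseases ‖ severities. Exactly one plant bit and one
severity bit are set; exactly one disease bit is set unless the severity is
*Healthy*, in which case the disease block is all-zero. This encoding is
forced by the vocabulary itself: the disease list contains no "healthy"
entry, and in the packaged count tables the disease column totals fall short
of the overall totals by exactly the Healthy counts (24,159 − 18,577 =
5,582 training images).

**Feature tokenizer.** A convolution with kernel = stride = patch size
(16 or 32) embeds each non-overlapping patch into a D-dimensional token;
learned position embeddings are added once, immediately after the patch
embedding; a depth-`depth` stack of transformer blocks mixes global context;
a same-padded 3×3 convolution over the h×w token grid (D→D channels)
re-injects local neighborhood structure. Token order is row-major from the
top-left, and the token count is invariant through every stage after
patchify — properties the tests pin down because the GradCAM overlay and the
grid reshape depend on them. The patch-splitting convolution and the
trailing convolution are separate operators; 3×3 is the smallest kernel
that adds local context without changing the token count. There is no class
token: the decoder's label queries do all the readout.

**Transformer blocks.** Pre-norm residual composition, layer normalization
over the channel axis, multi-head attention with d_k = D/heads per head and
1/√d_k score scaling, and a GELU MLP of width `mlp_ratio·D` with dropout
(rate 0.1 at the full profile, 0 at the tiny profile) inside the MLP and on
attention outputs. Pre-norm was chosen for training stability; the
oracle-equality tests encode this composition explicitly, so the choice is
load-bearing and documented rather than incidental. Q/K/V projections are
stored as single D×D matrices whose column blocks are the per-head
projections; the brute-force test oracles split them head by head.

**Token encoder and fusion.** The token encoder applies 0–2 of these blocks
(default 2). Its output is summed elementwise with its input — the
tokenizer's compact tokens — to form the fused tokens. Addition rather than
concatenation keeps the residual reading of the shortcut and the shapes
already agree; with 0 encoder blocks the fusion degenerates to doubling,
which the tests use as a contract.

**Label-query decoder.** A bank of `n_labels` learnable queries
(init N(0, 0.02²)) passes through 1–3 decoder blocks (default 2): self-
attention over the queries, cross-attention with the fused tokens as keys
and values (the same fused sequence for every block), then an MLP, all
pre-norm residual. The head maps query i to logit i by an independent dot
product — no cross-label mixing — so each query owns one label. Scores are
elementwise sigmoids: the labels are not mutually exclusive (a *Serious*
and a *General* score can both be near 1 on a confusable image), which
rules out a softmax across the vocabulary.

**Decoding and metrics.** decode = per-group argmax, ties to the lowest
index, disease gated to "none" when the predicted severity is *Healthy*.
Disease accuracy on a healthy-truth sample counts as correct iff the
prediction is also healthy; this gating is a package decision (the
convention is not derivable from the vocabulary alone). Weighted P/R/F1 are
computed over the binary labels at a 0.5 sigmoid threshold with supports as
weights, with 0 conventions on empty denominators; the per-label aggregation
level (rather than over joint classes) matches reporting P/R/F1 ≈ 95 %
alongside PDSA ≈ 87 % at full scale, which only per-label aggregation
produces. PDSA is the fraction of exactly-correct triples and is provably
≤ every group accuracy.

## Training

Per-label sigmoid binary cross-entropy, averaged over batch and labels, is
the loss — the natural pairing with multi-hot targets and sigmoid scores.
AdamW (decoupled weight decay, default 1e-4) under a step schedule
lr(e) = base_lr · gamma^⌊e/step⌋. The full-profile defaults are the
reference recipe: 60 epochs, batch 16, base_lr 6.25e-6, step 4, gamma 0.5,
five repeated runs averaged. That learning rate is characteristic of
fine-tuning from pretrained weights; this package supports cold starts and
user-supplied weights but downloads nothing, so the tiny profile trains
cold at 1e-3–2e-3. Augmentation is a random resized crop (area scale
0.5–1.0, aspect 3/4–4/3) to the working resolution plus a p = 0.5
horizontal flip; evaluation uses a plain bilinear resize. Pixels are
normalized per channel as (x − 0.5)/0.5. A single integer seed drives
initialization, shuffling, augmentation and dropout, and two runs with the
same seed are bit-identical.

## The tensor engine

No deep-learning framework is declared; the network runs on a small
reverse-mode autodiff over float64 NumPy arrays (`ldinet.autodiff`)
implementing exactly the operations the model needs (broadcast arithmetic,
batched matmul, softmax, layer norm, erf-GELU, sigmoid/BCE-with-logits, an
im2col same-padded convolution, dropout). float64 keeps the oracle
comparisons tight (1e-5 to 1e-12 in the tests) and the model sizes here
(~10⁵ parameters at the tiny profile) make the speed penalty irrelevant.
Correctness is established two ways: nested-loop brute-force oracles for
every algebraic operation, and a whole-model directional-derivative check
against finite differences.

## Synthetic data

The generator emulates a three-factor image population in which each label
group is independently decodable from pixels:

* plant → background hue and leaf-silhouette aspect ratio,
* disease → lesion motif (spot/ring/streak) and lesion hue,
* severity → lesion area fraction: Healthy exactly 0, General in
  [0.04, 0.10], Serious in [0.15, 0.30] of image area (disjoint bands).

Lesions are stamped at seeded positions on the leaf until the coverage
target inside the band is reached; additive Gaussian pixel noise
(sd 0.02 by default) is applied last. Everything derives deterministically
from the spec seed (per-sample seeds by hashing), so datasets are
byte-reproducible. A pixel-statistic oracle in the tests recovers the true
triple on 100 % of noise-free samples, which is what makes tiny-model
learnability a meaningful acceptance surface: a model that cannot memorize
64 separable images is broken. What the synthetic population deliberately
lacks — field backgrounds, lighting and pose variation, correlated factors,
photorealistic texture — means passing tests demonstrate the pipeline and
the architecture's capacity, not field performance on photographs.

Default desk-scale conditions: 64×64 images (divisible by both supported
patch sizes), 3 plants × 2 diseases, 64 images for the overfit harness,
balanced counts unless a table-ratio profile is requested
(`table_ratio_counts` mimics the reference severity imbalance
Healthy:General:Serious ≈ 5582:7600:10977).

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely at the tiny profile:
32-dim, 2-block tokenizer, 2 encoder + 2 decoder blocks, 16 tokens per
64×64 image. The overfit harness trains 100 epochs at base_lr 2e-3
(step 40) without augmentation and evaluates on its own training set; the
ablation grid trains each of the nine encoder×decoder combinations for 30
epochs on the same 64-image set with an 80/20 stratified split. These sizes
were chosen so the whole suite completes in well under a minute of compute
per component while still exercising every code path end to end.

## Numerical and design choices

* Round-half-up per-class rounding in the stratified split; the reference
  24,159/6,054 counts are then matched only approximately, since the
  reference split of 30,210 images is itself not exactly 80 %.
* Ties in argmax decoding break toward the lowest index (determinism).
* Zero-denominator P/R/F1 convention: 0.
* GradCAM targets the fused tokens — the last spatial representation before
  the query decoder — with channel weights = spatial mean of the gradient,
  ReLU, max-normalization (a nonzero map peaks at exactly 1), bilinear
  upsampling, jet-style red-high/blue-low overlay.
* Manifests are UTF-8 header CSV (`path,plant,disease,severity`, empty
  disease = healthy); YAML configs reject unknown keys loudly because a
  silently ignored typo can invalidate an ablation grid.
* Checkpoints are self-describing (`.npz` with parameters, model config and
  label space), so `evaluate`/`predict`/`gradcam` need no side information.

## Known limitations

* No pretrained weights, so full-profile (224 px, 768-dim) training from
  scratch is supported but not demonstrated; all shipped evidence is
  desk-scale.
* The synthetic factors are independent by construction; real
  plant-disease co-occurrence structure (not every disease infects every
  plant) is not modeled, and the decoder's cross-label correlations are
  therefore only weakly exercised.
* The per-query scalar readout is one of several defensible heads; a
  query-to-D MLP followed by a separate projection would also fit the
  architecture description.
* float64 NumPy wins no speed records; the package targets correctness and
  CPU-scale experiments, not GPU-scale training.
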