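# ldinet

Single-branch multi-label identification of **plant type, leaf disease and
severity** from leaf images.

Leaf-disease recognition systems usually either enumerate every joint
plant-disease-severity combination as one class (which multiplies the number
of categories and starves each of data) or split the three factors across
separate network branches (which multiplies parameters). `ldinet` implements
the alternative: one straightforward branch that scores a **multi-hot label
vector** — for the reference vocabulary, 34 binary labels = 12 plants ‖ 19
diseases ‖ 3 severities (*Healthy*, *General*, *Serious*). A diseased image
carries three positive labels (e.g. *Tomato*, *Late Blight*, *Serious*); a
healthy image carries two (its plant and *Healthy* — "healthy" is not a
disease).

The network (LDI-NET) has three stages:

1. **Feature tokenizer** — a strided patch convolution (patch size 16 or 32)
   with learned position embeddings, a stack of transformer blocks for
   long-range context, then a same-padded 3×3 convolution over the token
   grid for local structure:
   `Y = Conv2d(TB … TB(Conv2d(I)))`,
   producing compact spatial feature tokens `Y ∈ ℝ^{L×D}`, `L = (H/ps)²`.
2. **Token encoder** — two pre-norm transformer blocks
   (`X' = X + MSA(LN(X))`, `out = X' + MLP(LN(X'))`) with
   `SA(Q,K,V) = softmax(QKᵀ/√d_k)V`, yielding context-rich tokens.
3. **Label-query decoder** — one learnable query ("adaptive feature
   embedding") per label. Each of the two decoder blocks runs self-attention
   over the queries, cross-attention from queries to the **fused tokens**
   (elementwise sum of compact and context-rich tokens — a residual
   shortcut past the encoder), and an MLP. A per-label scalar projection
   and an elementwise sigmoid give independent label scores.

A triple is read out by per-group argmax, with the disease gated off when
the predicted severity is *Healthy*. Evaluation reports support-weighted
precision/recall/F1 over the binary labels plus per-group accuracies and
**PDSA** (plant-disease-severity accuracy: the fraction of images whose full
triple is correct; always ≤ each group accuracy).

The tensor engine is a compact NumPy reverse-mode autodiff (`ldinet.autodiff`)
— the model, AdamW, and GradCAM all run on it, so the package has no deep
learning framework dependency. Because the reference photographs (AI
Challenger 2018) are not redistributable, the package ships a **synthetic
leaf-image generator** whose three visual factors (background/silhouette,
lesion motif, lesion coverage band) map one-to-one onto the three label
groups, making end-to-end learnability testable on any machine. The
per-category image counts of the reference dataset are packaged as CSV count
tables (`ldinet/data/`).

## Worked example

Generate a synthetic dataset (3 plants × 2 diseases, 120 images at 64×64),
train the tiny profile, evaluate, and inspect one prediction:

```bash
ldinet generate-data --spec-file spec.yaml --out-dir data --seed 7
ldinet train --config-file train.yaml
ldinet evaluate --checkpoint run/checkpoint.npz \
                --manifest data/manifest.csv --out-dir eval
ldinet predict --checkpoint run/checkpoint.npz \
               --image data/images/plant_00_disease_00_serious_0000.png
```

with `spec.yaml` the default synthetic spec at `class_counts` of 8 per
triple, and `train.yaml`:

```yaml
profile: tiny
train: {epochs: 120, base_lr: 2.0e-3, lr_step: 50}
manifest: data/manifest.csv
out_dir: run
seed: 0
```

On one CPU this takes about 20 s and prints:

```
final val PDSA 80.00%
{
  "precision": 96.79, "recall": 97.32, "f1": 97.05,
  "plant_accuracy": 100.0, "disease_accuracy": 93.33,
  "severity_accuracy": 99.17, "pdsa": 92.5
}
Serious      1.000
plant_00     1.000
disease_00   0.999
disease_01   0.002
plant_01     0.000
plant_02     0.000
General      0.000
triple  plant_00 / disease_00 / Serious
```

The evaluation block is the training-manifest report (92.5 % of images get
the entire triple right; each group accuracy bounds PDSA from above). The
prediction lists the top-7 label scores — the true triple's three labels
score ≈ 1 and all others ≈ 0, which is exactly the independent-sigmoid
behaviour the multi-label head is designed for.

Other commands: `ldinet gradcam` writes an attention overlay PNG for any
label, and `ldinet ablate` trains the nine encoder×decoder combinations
(encoder blocks 0–2 × decoder blocks 1–3) and writes the grid as CSV.

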