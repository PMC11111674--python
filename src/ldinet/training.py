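"""Loss, schedule, augmentation, the training loop and checkpoints.

Training minimizes a per-label sigmoid binary cross-entropy: each of the
labels is an independent binary decision, matching the multi-hot targets and
the sigmoid score readout.  Optimization is AdamW under a step-decay schedule

    lr(e) = base_lr · gamma^floor(e / step)

with defaults taken from the reference training recipe (60 epochs, batch 16,
base_lr 6.25e-6, step 4, gamma 0.5, five repeated runs).  The reference
recipe fine-tunes at that very low rate; cold-start desk-scale runs use a
larger configurable rate.  Augmentation is a random resized crop followed by
a random horizontal flip; evaluation uses a plain deterministic resize.
Pixels are normalized per channel as (x − 0.5)/0.5.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import AdamW, Tensor
from .feature_tokenizer import TokenizerConfig
from .label_space import LabelSpace, encode_triple
from .metrics import MetricsReport, evaluate_predictions
from .multilabel_decoder import LDINet, ModelConfig

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "multilabel_loss",
    "lr_at_epoch",
    "augment_train",
    "eval_transform",
    "normalize_pixels",
    "load_records",
    "train",
    "repeat_runs",
    "evaluate_model",
    "predict_scores",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 16
    base_lr: float = 6.25e-6
    lr_step: int = 4
    lr_gamma: float = 0.5
    weight_decay: float = 1e-4
    seed: int = 0
    n_repeats: int = 5
    image_size: int = 224

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_step, self.n_repeats,
               self.image_size) < 1:
            raise ValueError("epochs, batch_size, lr_step, n_repeats, image_size "
                             "must be positive")
        if self.base_lr <= 0 or self.weight_decay < 0:
            raise ValueError("base_lr must be positive, weight_decay non-negative")
        if not 0.0 < self.lr_gamma <= 1.0:
            raise ValueError("lr_gamma must be in (0, 1]")


@dataclass
class TrainHistory:
    losses: list = field(default_factory=list)           # one per epoch
    val_reports: list = field(default_factory=list)      # MetricsReport per epoch
    lrs: list = field(default_factory=list)              # lr used per epoch

    def to_csv(self, path) -> None:
        lines = ["epoch,lr,train_loss,val_pdsa,val_f1"]
        for e, (lr, loss, rep) in enumerate(zip(self.lrs, self.losses, self.val_reports)):
            lines.append(f"{e},{lr:.8g},{loss:.6f},{rep.pdsa:.2f},{rep.f1:.2f}")
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# loss and schedule
# --------------------------------------------------------------------------

def multilabel_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy between sigmoid(logits) and multi-hot targets."""
    t = np.asarray(targets)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("targets must be binary")
    if logits.shape != t.shape:
        raise ValueError(f"logits {logits.shape} and targets {t.shape} differ")
    return logits.bce_with_logits(t)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step decay: base_lr · gamma^floor(epoch/step)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return config.base_lr * config.lr_gamma ** (epoch // config.lr_step)


# --------------------------------------------------------------------------
# image transforms
# --------------------------------------------------------------------------

def _resize(image: np.ndarray, size: int) -> np.ndarray:
    arr = np.clip(image, 0.0, 1.0)
    pil = Image.fromarray(np.round(arr * 255.0).astype(np.uint8))
    out = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(out, dtype=np.float64) / 255.0


def augment_train(image: np.ndarray, rng: np.random.Generator,
                  image_size: int) -> np.ndarray:
    """Random resized crop to image_size², then horizontal flip with p = 0.5."""
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image too small to crop")
    for _ in range(10):
        scale = rng.uniform(0.5, 1.0)
        log_aspect = rng.uniform(np.log(3 / 4), np.log(4 / 3))
        area = scale * h * w
        cw = int(round(np.sqrt(area * np.exp(log_aspect))))
        ch = int(round(np.sqrt(area / np.exp(log_aspect))))
        if 0 < cw <= w and 0 < ch <= h:
            break
    else:
        ch, cw = h, w
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    crop = image[y0 : y0 + ch, x0 : x0 + cw]
    out = _resize(crop, image_size)
    if rng.random() < 0.5:
        out = out[:, ::-1].copy()
    return out


def eval_transform(image: np.ndarray, image_size: int) -> np.ndarray:
    """Deterministic resize (no crop)."""
    if image.shape[0] == image.shape[1] == image_size:
        return np.asarray(image, dtype=np.float64)
    return _resize(image, image_size)


def normalize_pixels(image: np.ndarray) -> np.ndarray:
    """Per-channel (x − 0.5)/0.5 → range [−1, 1]."""
    return (np.asarray(image, dtype=np.float64) - 0.5) / 0.5


# --------------------------------------------------------------------------
# data loading
# --------------------------------------------------------------------------

def load_records(records, root, space: LabelSpace):
    """Load manifest records into arrays: raw images, targets, triples."""
    root = Path(root)
    images, targets, triples = [], [], []
    for rec in records:
        path = root / rec.image_path
        if not path.exists():
            raise FileNotFoundError(f"image file missing: {path}")
        arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
        images.append(arr)
        targets.append(encode_triple(space, rec.triple))
        triples.append(rec.triple)
    return images, np.asarray(targets), triples


# --------------------------------------------------------------------------
# evaluation / prediction helpers
# --------------------------------------------------------------------------

def predict_scores(model: LDINet, images, batch_size: int = 32) -> np.ndarray:
    """Eval-mode scores for a list of raw [0,1] images (resized as needed)."""
    size = model.config.image_size
    prepped = np.stack([normalize_pixels(eval_transform(im, size)) for im in images])
    outs = []
    for i in range(0, len(prepped), batch_size):
        _, scores, _ = model.forward(prepped[i : i + batch_size], training=False)
        outs.append(scores.data)
    return np.concatenate(outs, axis=0)


def evaluate_model(model: LDINet, images, targets, triples,
                   space: LabelSpace, batch_size: int = 32) -> MetricsReport:
    scores = predict_scores(model, images, batch_size)
    return evaluate_predictions(space, scores, targets, triples)


# --------------------------------------------------------------------------
# the training loop
# --------------------------------------------------------------------------

def train(model: LDINet, train_records, val_records, config: TrainConfig,
          root, space: LabelSpace, augment: bool = True):
    """Mini-batch AdamW training; returns (model, TrainHistory).

    The global seed drives shuffling, augmentation and dropout.  Validation
    runs after every epoch with the deterministic eval transform.
    """
    if not train_records or not val_records:
        raise ValueError("train and validation record sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    tr_images, tr_targets, _ = load_records(train_records, root, space)
    va_images, va_targets, va_triples = load_records(val_records, root, space)

    opt = AdamW(model.parameters(), lr=config.base_lr,
                weight_decay=config.weight_decay)
    history = TrainHistory()
    size = config.image_size
    n = len(tr_images)

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if augment:
                batch = np.stack([
                    normalize_pixels(augment_train(tr_images[i], rng, size))
                    for i in idx])
            else:
                batch = np.stack([
                    normalize_pixels(eval_transform(tr_images[i], size))
                    for i in idx])
            logits, _, _ = model.forward(batch, training=True, rng=rng)
            loss = multilabel_loss(logits, tr_targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.losses.append(epoch_loss / max(n_batches, 1))
        history.lrs.append(lr)
        history.val_reports.append(
            evaluate_model(model, va_images, va_targets, va_triples, space))
    return model, history


def repeat_runs(model_factory, train_records, val_records, config: TrainConfig,
                root, space: LabelSpace, n_repeats: int | None = None,
                seeds=None) -> dict:
    """Repeat training with distinct seeds; report mean ± sd of final metrics.

    `model_factory(seed)` must build a freshly initialized model.  Returns
    {metric: (mean, sd)} over the final-epoch validation reports.
    """
    if n_repeats is None:
        n_repeats = config.n_repeats
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")

    finals = []
    for seed in seeds:
        cfg = TrainConfig(**{**config.__dict__, "seed": int(seed)})
        model = model_factory(int(seed))
        _, history = train(model, train_records, val_records, cfg, root, space)
        finals.append(history.val_reports[-1])

    out = {}
    for key in ("precision", "recall", "f1", "plant_accuracy",
                "disease_accuracy", "severity_accuracy", "pdsa"):
        vals = np.array([getattr(r, key) for r in finals])
        out[key] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def _tokenizer_config_dict(c: TokenizerConfig) -> dict:
    return {"patch_size": c.patch_size, "embed_dim": c.embed_dim, "depth": c.depth,
            "heads": c.heads, "mlp_ratio": c.mlp_ratio, "conv_kernel": c.conv_kernel,
            "dropout": c.dropout}


def model_config_to_dict(c: ModelConfig) -> dict:
    return {"tokenizer": _tokenizer_config_dict(c.tokenizer),
            "n_encoder_blocks": c.n_encoder_blocks,
            "n_decoder_blocks": c.n_decoder_blocks,
            "n_labels": c.n_labels, "image_size": c.image_size}


def model_config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(tokenizer=TokenizerConfig(**d["tokenizer"]),
                       n_encoder_blocks=d["n_encoder_blocks"],
                       n_decoder_blocks=d["n_decoder_blocks"],
                       n_labels=d["n_labels"], image_size=d["image_size"])


def save_checkpoint(model: LDINet, space: LabelSpace, path) -> None:
    """Self-describing checkpoint: all parameters + config + label space."""
    meta = json.dumps({"config": model_config_to_dict(model.config),
                       "label_space": space.to_dict()})
    arrays = {name: p.data for name, p in model.parameters().items()}
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.array(meta), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> tuple[LDINet, LabelSpace]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    config = model_config_from_dict(meta["config"])
    space = LabelSpace.from_dict(meta["label_space"])
    model = LDINet(config, rng=0)
    params = model.parameters()
    missing = set(params) ^ set(arrays)
    if missing:
        raise ValueError(f"checkpoint parameter mismatch: {sorted(missing)[:5]}")
    for name, p in params.items():
        if p.data.shape != arrays[name].shape:
            raise ValueError(f"shape mismatch for {name}")
        p.data[...] = arrays[name]
    return model, space
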