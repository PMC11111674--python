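"""Run configuration: profiles, YAML loading with strict key checking.

Two named profiles bundle coherent hyperparameter sets:

* ``paper`` — the reference recipe: 224×224 input, patch size 16, a
  12-block/768-dim tokenizer, 60 epochs, batch 16, base_lr 6.25e-6.
* ``tiny``  — desk-scale: 64×64 input, a 2-block/32-dim tokenizer, no
  dropout, and a cold-start learning rate of 1e-3, small enough to train
  on a CPU in seconds-to-minutes.

YAML files select a profile and may override individual keys; unknown keys
are rejected loudly, because a silently ignored typo can invalidate a whole
ablation grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .feature_tokenizer import TokenizerConfig
from .multilabel_decoder import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "PROFILES"]

PROFILES = {
    "paper": {
        "image_size": 224,
        "tokenizer": {"patch_size": 16, "embed_dim": 768, "depth": 12,
                      "heads": 12, "mlp_ratio": 4, "conv_kernel": 3,
                      "dropout": 0.1},
        "n_encoder_blocks": 2,
        "n_decoder_blocks": 2,
        "train": {"epochs": 60, "batch_size": 16, "base_lr": 6.25e-6,
                  "lr_step": 4, "lr_gamma": 0.5, "weight_decay": 1e-4,
                  "n_repeats": 5},
    },
    "tiny": {
        "image_size": 64,
        "tokenizer": {"patch_size": 16, "embed_dim": 32, "depth": 2,
                      "heads": 4, "mlp_ratio": 2, "conv_kernel": 3,
                      "dropout": 0.0},
        "n_encoder_blocks": 2,
        "n_decoder_blocks": 2,
        "train": {"epochs": 40, "batch_size": 16, "base_lr": 1e-3,
                  "lr_step": 15, "lr_gamma": 0.5, "weight_decay": 1e-4,
                  "n_repeats": 3},
    },
}

_TOP_KEYS = {"profile", "image_size", "tokenizer", "n_encoder_blocks",
             "n_decoder_blocks", "train", "manifest", "images_root",
             "out_dir", "seed"}
_TOKENIZER_KEYS = {"patch_size", "embed_dim", "depth", "heads", "mlp_ratio",
                   "conv_kernel", "dropout"}
_TRAIN_KEYS = {"epochs", "batch_size", "base_lr", "lr_step", "lr_gamma",
               "weight_decay", "n_repeats"}


class ConfigKeyError(ValueError):
    pass


def _check_keys(section: str, d: dict, allowed: set) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigKeyError(
            f"unknown key(s) in {section}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})")


@dataclass(frozen=True)
class RunConfig:
    profile: str = "tiny"
    image_size: int = 64
    tokenizer: dict = field(default_factory=lambda: dict(PROFILES["tiny"]["tokenizer"]))
    n_encoder_blocks: int = 2
    n_decoder_blocks: int = 2
    train: dict = field(default_factory=lambda: dict(PROFILES["tiny"]["train"]))
    manifest: str | None = None
    images_root: str | None = None
    out_dir: str = "runs"
    seed: int = 0

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "RunConfig":
        if profile not in PROFILES:
            raise ConfigKeyError(f"unknown profile {profile!r}; "
                                 f"choose from {sorted(PROFILES)}")
        base = PROFILES[profile]
        d = {"profile": profile,
             "image_size": base["image_size"],
             "tokenizer": dict(base["tokenizer"]),
             "n_encoder_blocks": base["n_encoder_blocks"],
             "n_decoder_blocks": base["n_decoder_blocks"],
             "train": dict(base["train"])}
        for k, v in overrides.items():
            if k in ("tokenizer", "train"):
                d[k].update(v)
            else:
                d[k] = v
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys(str(path), raw, _TOP_KEYS)
        if "tokenizer" in raw:
            _check_keys(f"{path}:tokenizer", raw["tokenizer"], _TOKENIZER_KEYS)
        if "train" in raw:
            _check_keys(f"{path}:train", raw["train"], _TRAIN_KEYS)
        profile = raw.pop("profile", "tiny")
        return cls.from_profile(profile, **raw)

    # -- derived configs ----------------------------------------------------
    def model_config(self, n_labels: int) -> ModelConfig:
        return ModelConfig(
            tokenizer=TokenizerConfig(**self.tokenizer),
            n_encoder_blocks=self.n_encoder_blocks,
            n_decoder_blocks=self.n_decoder_blocks,
            n_labels=n_labels,
            image_size=self.image_size,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(image_size=self.image_size, seed=self.seed,
                           **self.train)

    def to_dict(self) -> dict:
        return {"profile": self.profile, "image_size": self.image_size,
                "tokenizer": dict(self.tokenizer),
                "n_encoder_blocks": self.n_encoder_blocks,
                "n_decoder_blocks": self.n_decoder_blocks,
                "train": dict(self.train), "manifest": self.manifest,
                "images_root": self.images_root, "out_dir": self.out_dir,
                "seed": self.seed}

    def digest(self) -> str:
        """Stable hash of the full configuration, for reproducibility logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
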