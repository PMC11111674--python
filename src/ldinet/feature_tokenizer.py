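"""Hybrid conv/transformer feature tokenizer.

The tokenizer turns an H×W×3 image into compact spatial feature tokens in
four steps: (1) a strided "patchify" convolution (kernel = stride =
patch_size, 16 or 32) maps each non-overlapping patch to one D-dim token;
(2) learned position embeddings are added to restore spatial order; (3) a
stack of transformer blocks mixes long-range context; (4) a same-padded 3×3
convolution over the token grid re-injects local neighborhood structure.
Token order is row-major with the origin at the top-left, and the token
count L = (H/ps)·(W/ps) is invariant through steps 2–4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor
from .transformer_core import (
    ConfigError,
    EncoderBlockParams,
    encoder_block,
    init_encoder_block,
)

__all__ = [
    "TokenizerConfig",
    "TokenizerParams",
    "TokenSequence",
    "patchify_embed",
    "add_position_embeddings",
    "local_refine",
    "tokenize",
    "init_tokenizer",
]

SUPPORTED_PATCH_SIZES = (16, 32)


@dataclass(frozen=True)
class TokenizerConfig:
    """Hyperparameters of the tokenizer.

    The transformer-stack scale (depth/dim/heads) follows standard visual
    transformer practice at the default profile; the tiny profile is meant for
    CPU tests and desk-scale experiments.
    """

    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    heads: int = 12
    mlp_ratio: int = 4
    conv_kernel: int = 3
    dropout: float = 0.1

    def __post_init__(self):
        if self.patch_size not in SUPPORTED_PATCH_SIZES:
            raise ConfigError(f"patch_size must be one of {SUPPORTED_PATCH_SIZES}")
        if self.embed_dim % self.heads:
            raise ConfigError("embed_dim must be divisible by heads")
        if self.conv_kernel % 2 == 0:
            raise ConfigError("conv_kernel must be odd")
        if self.depth < 0:
            raise ConfigError("depth must be non-negative")


TINY_TOKENIZER = TokenizerConfig(patch_size=16, embed_dim=32, depth=2, heads=4,
                                 mlp_ratio=2, conv_kernel=3, dropout=0.0)


@dataclass
class TokenSequence:
    """Tokens (B, L, D) plus their 2-D grid arrangement (h, w), h·w = L."""

    tokens: Tensor
    grid: tuple[int, int]

    def __post_init__(self):
        h, w = self.grid
        if self.tokens.shape[-2] != h * w:
            raise ConfigError(
                f"token count {self.tokens.shape[-2]} != grid {h}×{w}")


@dataclass
class TokenizerParams:
    patch_W: Parameter           # (ps·ps·3) × D
    patch_b: Parameter           # D
    pos_embed: Parameter         # L × D (tied to a fixed image size)
    blocks: list[EncoderBlockParams] = field(default_factory=list)
    conv_W: Parameter = None     # (k·k·D) × D
    conv_b: Parameter = None     # D


def init_tokenizer(config: TokenizerConfig, image_size: int,
                   rng: np.random.Generator) -> TokenizerParams:
    if image_size % config.patch_size:
        raise ConfigError(
            f"image size {image_size} not divisible by patch size {config.patch_size}")
    ps, d = config.patch_size, config.embed_dim
    g = image_size // ps
    return TokenizerParams(
        patch_W=Parameter(rng.normal(0.0, 0.02, (ps * ps * 3, d))),
        patch_b=Parameter(np.zeros(d)),
        pos_embed=Parameter(rng.normal(0.0, 0.02, (g * g, d))),
        blocks=[init_encoder_block(d, config.heads, config.mlp_ratio, rng,
                                   config.dropout)
                for _ in range(config.depth)],
        conv_W=Parameter(rng.normal(0.0, 0.02,
                                    (config.conv_kernel ** 2 * d, d))),
        conv_b=Parameter(np.zeros(d)),
    )


def patchify_embed(images: Tensor | np.ndarray, config: TokenizerConfig,
                   params: TokenizerParams) -> TokenSequence:
    """Strided patch convolution: each ps×ps×3 patch → one D-dim token.

    Accepts (B, H, W, 3) or a single (H, W, 3) image.
    """
    x = Tensor.as_tensor(images)
    single = x.ndim == 3
    if single:
        x = x.reshape(1, *x.shape)
    b, h, w, c = x.shape
    ps = config.patch_size
    if h % ps or w % ps:
        raise ConfigError(f"image {h}×{w} not divisible by patch size {ps}")
    gh, gw = h // ps, w // ps
    # (B, gh, ps, gw, ps, C) → (B, gh, gw, ps, ps, C) → (B, L, ps·ps·C)
    patches = (x.reshape(b, gh, ps, gw, ps, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(b, gh * gw, ps * ps * c))
    tokens = patches @ params.patch_W + params.patch_b
    return TokenSequence(tokens, (gh, gw))


def add_position_embeddings(seq: TokenSequence, pe: Tensor) -> TokenSequence:
    """Elementwise sum of the learned position table with every batch item."""
    if pe.shape != seq.tokens.shape[-2:]:
        raise ConfigError(
            f"position embedding shape {pe.shape} != token shape {seq.tokens.shape[-2:]}")
    return TokenSequence(seq.tokens + pe, seq.grid)


def local_refine(seq: TokenSequence, config: TokenizerConfig,
                 params: TokenizerParams) -> TokenSequence:
    """Same-padded conv over the h×w token grid (D→D channels), row-major."""
    h, w = seq.grid
    b, l, d = seq.tokens.shape
    grid = seq.tokens.reshape(b, h, w, d)
    refined = grid.conv2d_same(params.conv_W, params.conv_b, config.conv_kernel)
    return TokenSequence(refined.reshape(b, l, d), seq.grid)


def tokenize(images: Tensor | np.ndarray, config: TokenizerConfig,
             params: TokenizerParams, training: bool = False,
             rng: np.random.Generator | None = None) -> TokenSequence:
    """Full tokenizer: patchify → +position → transformer stack → local conv."""
    seq = patchify_embed(images, config, params)
    seq = add_position_embeddings(seq, params.pos_embed)
    tokens = seq.tokens
    for blk in params.blocks:
        tokens = encoder_block(tokens, blk, training, rng)
    return local_refine(TokenSequence(tokens, seq.grid), config, params)
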