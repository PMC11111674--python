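"""Label-query decoder, residual token fusion and the assembled network.

The decoder owns one learnable query vector ("adaptive feature embedding")
per label.  Each decoder block runs

    Q'  = Q  + MSA_self(LN(Q))                 (queries attend to each other)
    Q'' = Q' + MCA(LN(Q'), fused, fused)       (queries attend to the image)
    out = Q'' + MLP(LN(Q''))

where the cross-attention keys/values are the *fused* tokens — the
elementwise sum of the tokenizer's compact tokens (low-level features) and
the token encoder's context-rich tokens (high-level features).  The same
fused sequence feeds every decoder block.  A per-label scalar projection
turns the final queries into logits; scores are elementwise sigmoids, so
labels are scored independently rather than competing in one softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor
from .feature_tokenizer import (
    TokenizerConfig,
    TokenizerParams,
    TokenSequence,
    init_tokenizer,
    tokenize,
)
from .transformer_core import (
    AttentionParams,
    ConfigError,
    EncoderBlockParams,
    LayerNormParams,
    MLPParams,
    init_attention,
    init_encoder_block,
    init_layer_norm,
    init_mlp,
    mlp_forward,
    multi_head_attention,
    token_encoder,
)

__all__ = [
    "ModelConfig",
    "DecoderBlockParams",
    "LDINet",
    "fuse_tokens",
    "decoder_block",
    "readout",
    "ldi_net_forward",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The default of two token-encoder blocks and two decoder blocks is the
    configuration that performs best in the 3×3 encoder/decoder ablation
    grid; the grid itself (encoder 0–2 × decoder 1–3) stays supported.
    """

    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    n_encoder_blocks: int = 2
    n_decoder_blocks: int = 2
    n_labels: int = 34
    image_size: int = 224

    def __post_init__(self):
        if not 0 <= self.n_encoder_blocks <= 2:
            raise ConfigError("n_encoder_blocks must be in [0, 2]")
        if not 1 <= self.n_decoder_blocks <= 3:
            raise ConfigError("n_decoder_blocks must be in [1, 3]")
        if self.n_labels < 1:
            raise ConfigError("n_labels must be positive")
        if self.image_size % self.tokenizer.patch_size:
            raise ConfigError("image_size must be divisible by patch_size")


@dataclass
class DecoderBlockParams:
    self_attn: AttentionParams
    cross_attn: AttentionParams
    mlp: MLPParams
    ln1: LayerNormParams
    ln2: LayerNormParams
    ln3: LayerNormParams
    dropout: float = 0.1


def init_decoder_block(d: int, heads: int, mlp_ratio: int,
                       rng: np.random.Generator, dropout: float = 0.1) -> DecoderBlockParams:
    return DecoderBlockParams(
        init_attention(d, heads, rng),
        init_attention(d, heads, rng),
        init_mlp(d, mlp_ratio, rng, dropout),
        init_layer_norm(d),
        init_layer_norm(d),
        init_layer_norm(d),
        dropout,
    )


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def fuse_tokens(compact: TokenSequence, context_rich: TokenSequence) -> TokenSequence:
    """Residual fusion: elementwise sum of shallow and deep tokens."""
    if compact.tokens.shape != context_rich.tokens.shape or compact.grid != context_rich.grid:
        raise ConfigError("compact and context-rich token sequences must match in shape")
    return TokenSequence(compact.tokens + context_rich.tokens, compact.grid)


def decoder_block(queries: Tensor, fused: Tensor, params: DecoderBlockParams,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """One label-query decoder block (self-attn, cross-attn, MLP; pre-norm)."""
    n1 = queries.layer_norm(params.ln1.gamma, params.ln1.beta)
    q = queries + multi_head_attention(n1, n1, n1, params.self_attn).dropout(
        params.dropout, rng, training)
    n2 = q.layer_norm(params.ln2.gamma, params.ln2.beta)
    q = q + multi_head_attention(n2, fused, fused, params.cross_attn).dropout(
        params.dropout, rng, training)
    n3 = q.layer_norm(params.ln3.gamma, params.ln3.beta)
    return q + mlp_forward(n3, params.mlp, training, rng)


def readout(queries: Tensor, head_W: Tensor, head_b: Tensor) -> Tensor:
    """Per-label scalar logits: logit_i = w_i · query_i + b_i (no label mixing)."""
    return (queries * head_W).sum(axis=-1) + head_b


# --------------------------------------------------------------------------
# the assembled network
# --------------------------------------------------------------------------

class LDINet:
    """Single-branch multi-label network: tokenizer → encoder → query decoder."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.config = config
        d = config.tokenizer.embed_dim
        heads = config.tokenizer.heads
        ratio = config.tokenizer.mlp_ratio
        drop = config.tokenizer.dropout
        self.tokenizer_params: TokenizerParams = init_tokenizer(
            config.tokenizer, config.image_size, rng)
        self.encoder_blocks: list[EncoderBlockParams] = [
            init_encoder_block(d, heads, ratio, rng, drop)
            for _ in range(config.n_encoder_blocks)]
        self.queries = Parameter(rng.normal(0.0, 0.02, (config.n_labels, d)))
        self.decoder_blocks: list[DecoderBlockParams] = [
            init_decoder_block(d, heads, ratio, rng, drop)
            for _ in range(config.n_decoder_blocks)]
        self.head_W = Parameter(rng.normal(0.0, 0.02, (config.n_labels, d)))
        self.head_b = Parameter(np.zeros(config.n_labels))

    # -- parameter bookkeeping ---------------------------------------------
    def parameters(self) -> dict[str, Parameter]:
        params: dict[str, Parameter] = {}

        def add(prefix, obj):
            if isinstance(obj, Parameter):
                params[prefix] = obj
            elif isinstance(obj, (AttentionParams,)):
                for n in ("W_Q", "W_K", "W_V", "W_O"):
                    params[f"{prefix}.{n}"] = getattr(obj, n)
            elif isinstance(obj, MLPParams):
                for n in ("W1", "b1", "W2", "b2"):
                    params[f"{prefix}.{n}"] = getattr(obj, n)
            elif isinstance(obj, LayerNormParams):
                params[f"{prefix}.gamma"] = obj.gamma
                params[f"{prefix}.beta"] = obj.beta
            elif isinstance(obj, EncoderBlockParams):
                add(f"{prefix}.attn", obj.attn)
                add(f"{prefix}.mlp", obj.mlp)
                add(f"{prefix}.ln1", obj.ln1)
                add(f"{prefix}.ln2", obj.ln2)
            elif isinstance(obj, DecoderBlockParams):
                add(f"{prefix}.self_attn", obj.self_attn)
                add(f"{prefix}.cross_attn", obj.cross_attn)
                add(f"{prefix}.mlp", obj.mlp)
                add(f"{prefix}.ln1", obj.ln1)
                add(f"{prefix}.ln2", obj.ln2)
                add(f"{prefix}.ln3", obj.ln3)
            else:
                raise TypeError(f"unknown parameter group {type(obj)}")

        tp = self.tokenizer_params
        add("tok.patch_W", tp.patch_W)
        add("tok.patch_b", tp.patch_b)
        add("tok.pos_embed", tp.pos_embed)
        for i, blk in enumerate(tp.blocks):
            add(f"tok.block{i}", blk)
        add("tok.conv_W", tp.conv_W)
        add("tok.conv_b", tp.conv_b)
        for i, blk in enumerate(self.encoder_blocks):
            add(f"enc.block{i}", blk)
        add("queries", self.queries)
        for i, blk in enumerate(self.decoder_blocks):
            add(f"dec.block{i}", blk)
        add("head_W", self.head_W)
        add("head_b", self.head_b)
        return params

    def forward(self, images, training: bool = False,
                rng: np.random.Generator | None = None):
        return ldi_net_forward(images, self, training, rng)

    def __call__(self, images, training: bool = False,
                 rng: np.random.Generator | None = None):
        return self.forward(images, training, rng)


def ldi_net_forward(images, model: LDINet, training: bool = False,
                    rng: np.random.Generator | None = None):
    """Full forward pass.

    Returns ``(logits, scores, intermediates)`` where logits/scores are
    (B, n_labels) Tensors and intermediates keeps the compact, context-rich
    and fused token sequences (the fused tokens are the GradCAM target).
    """
    cfg = model.config
    compact = tokenize(images, cfg.tokenizer, model.tokenizer_params, training, rng)
    rich_tokens = token_encoder(compact.tokens, model.encoder_blocks, training, rng)
    rich = TokenSequence(rich_tokens, compact.grid)
    fused = fuse_tokens(compact, rich)

    b = fused.tokens.shape[0]
    q = model.queries.broadcast_to((b, *model.queries.shape))
    for blk in model.decoder_blocks:
        q = decoder_block(q, fused.tokens, blk, training, rng)
    logits = readout(q, model.head_W, model.head_b)
    scores = logits.sigmoid()
    intermediates = {"compact": compact, "context_rich": rich, "fused": fused,
                     "final_queries": q}
    return logits, scores, intermediates
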