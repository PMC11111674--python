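"""Attention algebra, MLP block and the token encoder.

All operations take and return :class:`~ldinet.autodiff.Tensor` objects with a
leading batch axis: token sequences are (B, L, D).  Blocks use the pre-norm
residual form

    X' = X + MSA(LN(X));   out = X' + MLP(LN(X'))

with layer normalization over the channel axis.  Multi-head projections are
stored as single D×D matrices whose column blocks are the per-head W_i^Q,
W_i^K, W_i^V; the concatenated heads are mixed by W_O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "AttentionParams",
    "MLPParams",
    "EncoderBlockParams",
    "project_qkv",
    "scaled_dot_attention",
    "multi_head_attention",
    "mlp_forward",
    "encoder_block",
    "token_encoder",
    "init_attention",
    "init_mlp",
    "init_encoder_block",
]

INIT_SD = 0.02  # gaussian init scale for all projection weights


class ConfigError(ValueError):
    pass


@dataclass
class AttentionParams:
    """Q/K/V projections (heads stacked into D×D blocks) and the output mix."""

    W_Q: Parameter  # D×D
    W_K: Parameter
    W_V: Parameter
    W_O: Parameter  # D×D
    heads: int

    def __post_init__(self):
        d = self.W_Q.shape[0]
        for w in (self.W_Q, self.W_K, self.W_V, self.W_O):
            if w.shape != (d, d):
                raise ConfigError(f"attention matrices must all be {d}×{d}")
        if self.heads < 1 or d % self.heads:
            raise ConfigError(f"embed dim {d} not divisible by heads {self.heads}")

    @property
    def d_model(self) -> int:
        return self.W_Q.shape[0]

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads


@dataclass
class MLPParams:
    """Two linear layers D → r·D → D with GELU between, dropout after each."""

    W1: Parameter
    b1: Parameter
    W2: Parameter
    b2: Parameter
    dropout: float = 0.1

    def __post_init__(self):
        d, hidden = self.W1.shape
        if self.W2.shape != (hidden, d):
            raise ConfigError("MLP layer shapes inconsistent")


@dataclass
class LayerNormParams:
    gamma: Parameter
    beta: Parameter


@dataclass
class EncoderBlockParams:
    attn: AttentionParams
    mlp: MLPParams
    ln1: LayerNormParams
    ln2: LayerNormParams
    dropout: float = 0.1


# --------------------------------------------------------------------------
# initializers
# --------------------------------------------------------------------------

def init_attention(d: int, heads: int, rng: np.random.Generator) -> AttentionParams:
    def w():
        return Parameter(rng.normal(0.0, INIT_SD, (d, d)))
    return AttentionParams(w(), w(), w(), w(), heads)


def init_mlp(d: int, mlp_ratio: int, rng: np.random.Generator,
             dropout: float = 0.1) -> MLPParams:
    hidden = mlp_ratio * d
    return MLPParams(
        Parameter(rng.normal(0.0, INIT_SD, (d, hidden))),
        Parameter(np.zeros(hidden)),
        Parameter(rng.normal(0.0, INIT_SD, (hidden, d))),
        Parameter(np.zeros(d)),
        dropout,
    )


def init_layer_norm(d: int) -> LayerNormParams:
    return LayerNormParams(Parameter(np.ones(d)), Parameter(np.zeros(d)))


def init_encoder_block(d: int, heads: int, mlp_ratio: int,
                       rng: np.random.Generator, dropout: float = 0.1) -> EncoderBlockParams:
    return EncoderBlockParams(
        init_attention(d, heads, rng),
        init_mlp(d, mlp_ratio, rng, dropout),
        init_layer_norm(d),
        init_layer_norm(d),
        dropout,
    )


# --------------------------------------------------------------------------
# attention
# --------------------------------------------------------------------------

def project_qkv(x_q: Tensor, x_k: Tensor, x_v: Tensor,
                params: AttentionParams) -> tuple[Tensor, Tensor, Tensor]:
    """Linear Q/K/V projections (all heads at once)."""
    return x_q @ params.W_Q, x_k @ params.W_K, x_v @ params.W_V


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q·Kᵀ/√d_k)·V over the last two axes (any leading batch axes)."""
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ConfigError(f"query dim {d_k} != key dim {k.shape[-1]}")
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) / np.sqrt(d_k)
    return scores.softmax(axis=-1) @ v


def _split_heads(x: Tensor, heads: int) -> Tensor:
    """(B, L, D) → (B, heads, L, d_k)."""
    b, l, d = x.shape
    return x.reshape(b, l, heads, d // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    """(B, heads, L, d_k) → (B, L, D)."""
    b, h, l, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dk)


def multi_head_attention(x_q: Tensor, x_k: Tensor, x_v: Tensor,
                         params: AttentionParams) -> Tensor:
    """Heads run scaled-dot attention in parallel; concat is mixed by W_O.

    Self-attention passes the same sequence for all three inputs; the decoder's
    cross-attention passes queries as x_q and fused tokens as x_k = x_v.
    """
    q, k, v = project_qkv(x_q, x_k, x_v, params)
    h = params.heads
    out = scaled_dot_attention(_split_heads(q, h), _split_heads(k, h), _split_heads(v, h))
    return _merge_heads(out) @ params.W_O


# --------------------------------------------------------------------------
# MLP and blocks
# --------------------------------------------------------------------------

def mlp_forward(x: Tensor, params: MLPParams, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
    """linear → GELU → dropout → linear → dropout (dropout inert in eval)."""
    if training and params.dropout > 0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")
    h = (x @ params.W1 + params.b1).gelu()
    h = h.dropout(params.dropout, rng, training)
    out = h @ params.W2 + params.b2
    return out.dropout(params.dropout, rng, training)


def encoder_block(tokens: Tensor, params: EncoderBlockParams,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Pre-norm residual block: self-attention then MLP."""
    normed = tokens.layer_norm(params.ln1.gamma, params.ln1.beta)
    attn = multi_head_attention(normed, normed, normed, params.attn)
    attn = attn.dropout(params.dropout, rng, training)
    x = tokens + attn
    normed2 = x.layer_norm(params.ln2.gamma, params.ln2.beta)
    return x + mlp_forward(normed2, params.mlp, training, rng)


def token_encoder(tokens: Tensor, blocks: list[EncoderBlockParams],
                  training: bool = False,
                  rng: np.random.Generator | None = None,
                  n_blocks: int | None = None) -> Tensor:
    """Sequential encoder blocks (default: all of `blocks`; 0 blocks = identity)."""
    if n_blocks is None:
        n_blocks = len(blocks)
    if n_blocks < 0:
        raise ConfigError("n_blocks must be non-negative")
    if n_blocks > len(blocks):
        raise ConfigError(f"requested {n_blocks} blocks but only {len(blocks)} provided")
    out = tokens
    for params in blocks[:n_blocks]:
        out = encoder_block(out, params, training, rng)
    return out
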