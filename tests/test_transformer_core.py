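"""Attention algebra, MLP and encoder blocks against nested-loop oracles."""

import numpy as np
import pytest

import _oracles as oracle
import ldinet as L
from ldinet.autodiff import Parameter, Tensor
from ldinet.transformer_core import (
    AttentionParams,
    ConfigError,
    init_attention,
    init_encoder_block,
    init_mlp,
)


def _identity_attention(d, heads=1):
    eye = lambda: Parameter(np.eye(d))
    return AttentionParams(eye(), eye(), eye(), eye(), heads)


class TestProjectQKV:
    def test_identity_projection(self, rng):
        x = Tensor(rng.normal(size=(3, 4)))
        q, k, v = L.project_qkv(x, x, x, _identity_attention(4))
        np.testing.assert_allclose(q.data, x.data)

    def test_zero_input(self):
        params = init_attention(4, 2, np.random.default_rng(0))
        z = Tensor(np.zeros((3, 4)))
        q, k, v = L.project_qkv(z, z, z, params)
        assert not q.data.any() and not k.data.any() and not v.data.any()

    def test_matches_loop_matmul_oracle(self, rng):
        params = init_attention(4, 2, rng)
        x = Tensor(rng.normal(size=(3, 4)))
        q, _, _ = L.project_qkv(x, x, x, params)
        np.testing.assert_allclose(
            q.data, oracle.matmul_loops(x.data, params.W_Q.data), atol=1e-12)


class TestScaledDotAttention:
    def test_single_key_returns_value_row(self, rng):
        q = Tensor(rng.normal(size=(4, 3)))
        k = Tensor(rng.normal(size=(1, 3)))
        v = Tensor(rng.normal(size=(1, 3)))
        out = L.scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data, np.tile(v.data, (4, 1)), atol=1e-12)

    def test_identical_keys_average_values(self, rng):
        q = Tensor(rng.normal(size=(2, 3)))
        k = Tensor(np.tile(rng.normal(size=(1, 3)), (5, 1)))
        v = Tensor(rng.normal(size=(5, 3)))
        out = L.scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(
            out.data, np.tile(v.data.mean(axis=0), (2, 1)), atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        q = Tensor(rng.normal(size=(2, 2)))
        k = Tensor(rng.normal(size=(3, 2)))
        v = Tensor(rng.normal(size=(3, 2)))
        out = L.scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(
            out.data, oracle.scaled_dot_attention_loops(q.data, k.data, v.data),
            atol=1e-6)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ConfigError):
            L.scaled_dot_attention(Tensor(rng.normal(size=(2, 3))),
                                   Tensor(rng.normal(size=(2, 4))),
                                   Tensor(rng.normal(size=(2, 4))))


class TestMultiHeadAttention:
    def test_single_head_identity_wo_reduces_to_sa(self, rng):
        d = 4
        params = init_attention(d, 1, rng)
        params.W_O.data[...] = np.eye(d)
        x = Tensor(rng.normal(size=(1, 5, d)))
        got = L.multi_head_attention(x, x, x, params)
        q, k, v = L.project_qkv(x, x, x, params)
        expect = L.scaled_dot_attention(
            q.reshape(5, d), k.reshape(5, d), v.reshape(5, d))
        np.testing.assert_allclose(got.data[0], expect.data, atol=1e-10)

    def test_zero_output_matrix(self, rng):
        params = init_attention(4, 2, rng)
        params.W_O.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 3, 4)))
        assert not L.multi_head_attention(x, x, x, params).data.any()

    def test_two_heads_match_head_by_head_oracle(self, rng):
        d, heads = 4, 2
        params = init_attention(d, heads, rng)
        x = Tensor(rng.normal(size=(1, 4, d)))
        got = L.multi_head_attention(x, x, x, params)
        expect = oracle.multi_head_attention_loops(
            x.data[0], x.data[0], x.data[0],
            params.W_Q.data, params.W_K.data, params.W_V.data,
            params.W_O.data, heads)
        np.testing.assert_allclose(got.data[0], expect, atol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigError):
            AttentionParams(Parameter(np.eye(4)), Parameter(np.eye(4)),
                            Parameter(np.eye(4)), Parameter(np.eye(4)), heads=3)


class TestMLP:
    def test_zero_weights_broadcast_second_bias(self, rng):
        params = init_mlp(3, 2, rng)
        for w in (params.W1, params.W2, params.b1):
            w.data[...] = 0.0
        params.b2.data[...] = np.array([1.0, -2.0, 3.0])
        out = L.mlp_forward(Tensor(rng.normal(size=(4, 3))), params)
        np.testing.assert_allclose(out.data, np.tile(params.b2.data, (4, 1)))

    def test_eval_mode_deterministic(self, rng):
        params = init_mlp(3, 2, rng, dropout=0.5)
        x = Tensor(rng.normal(size=(4, 3)))
        a = L.mlp_forward(x, params, training=False)
        b = L.mlp_forward(x, params, training=False)
        np.testing.assert_array_equal(a.data, b.data)

    def test_matches_scalar_gelu_oracle(self, rng):
        params = init_mlp(2, 2, rng, dropout=0.0)
        x = Tensor(rng.normal(size=(1, 2)))
        got = L.mlp_forward(x, params)
        expect = oracle.mlp_loops(x.data, params.W1.data, params.b1.data,
                                  params.W2.data, params.b2.data)
        np.testing.assert_allclose(got.data, expect, atol=1e-6)


class TestEncoderBlock:
    def test_zero_weights_pure_residual_identity(self, rng):
        params = init_encoder_block(4, 2, 2, rng, dropout=0.0)
        for p in (params.attn.W_O, params.mlp.W2, params.mlp.b2):
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(2, 5, 4)))
        out = L.encoder_block(x, params)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_output_shape_preserved(self, rng):
        params = init_encoder_block(8, 2, 2, rng)
        x = Tensor(rng.normal(size=(3, 6, 8)))
        assert L.encoder_block(x, params).shape == x.shape

    def test_equals_explicit_sub_op_composition(self, rng):
        params = init_encoder_block(4, 2, 2, rng, dropout=0.0)
        x = Tensor(rng.normal(size=(1, 4, 4)))
        got = L.encoder_block(x, params)
        n1 = x.layer_norm(params.ln1.gamma, params.ln1.beta)
        mid = x + L.multi_head_attention(n1, n1, n1, params.attn)
        n2 = mid.layer_norm(params.ln2.gamma, params.ln2.beta)
        expect = mid + L.mlp_forward(n2, params.mlp)
        np.testing.assert_allclose(got.data, expect.data, atol=1e-12)

    def test_layer_norm_matches_loop_oracle(self, rng):
        gamma = Parameter(rng.normal(size=4))
        beta = Parameter(rng.normal(size=4))
        x = Tensor(rng.normal(size=(3, 4)))
        got = x.layer_norm(gamma, beta)
        expect = oracle.layer_norm_loops(x.data, gamma.data, beta.data)
        np.testing.assert_allclose(got.data, expect, atol=1e-10)


class TestTokenEncoder:
    def test_zero_blocks_identity(self, rng):
        x = Tensor(rng.normal(size=(2, 5, 4)))
        out = L.token_encoder(x, [])
        np.testing.assert_array_equal(out.data, x.data)

    def test_two_blocks_equal_sequential_application(self, rng):
        blocks = [init_encoder_block(4, 2, 2, rng, dropout=0.0) for _ in range(2)]
        x = Tensor(rng.normal(size=(1, 5, 4)))
        got = L.token_encoder(x, blocks)
        expect = L.encoder_block(L.encoder_block(x, blocks[0]), blocks[1])
        np.testing.assert_allclose(got.data, expect.data, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        """Without position embeddings the encoder commutes with any token
        permutation — no positional information inside the blocks."""
        blocks = [init_encoder_block(4, 2, 2, rng, dropout=0.0) for _ in range(2)]
        x = rng.normal(size=(1, 6, 4))
        perm = rng.permutation(6)
        out = L.token_encoder(Tensor(x), blocks).data
        out_perm = L.token_encoder(Tensor(x[:, perm]), blocks).data
        np.testing.assert_allclose(out[:, perm], out_perm, atol=1e-10)

    def test_negative_blocks_rejected(self, rng):
        with pytest.raises(ConfigError):
            L.token_encoder(Tensor(rng.normal(size=(1, 2, 4))), [], n_blocks=-1)
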