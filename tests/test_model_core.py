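"""Oracle-equivalence and property tests for the network blocks.

Every block is checked against an independent straight-loop
implementation (explicit per-element arithmetic, no shared code) on
many random small instances, and against finite-difference gradients.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from chemrel.autodiff import Tensor
from chemrel.features import pad_batch
from chemrel.model import (
    AttentionParams,
    LSTMParams,
    LSTMState,
    ModelConfig,
    PoolingParams,
    RelationModel,
    attention_pool,
    bilstm_encode,
    lstm_step,
    multihead_attention,
    scaled_dot_attention,
)
from chemrel.pipeline import build_dataset, pretrain_bilm


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def lstm_step_oracle(x, h_prev, c_prev, p: LSTMParams, variant="standard"):
    """Per-element loop over the gate equations."""
    H = p.hidden_size
    f = np.empty(H)
    o = np.empty(H)
    g = np.empty(H)
    i_ = np.empty(H)
    c = np.empty(H)
    h = np.empty(H)
    for j in range(H):
        zf = sum(x[k] * p.W_f.data[k, j] for k in range(len(x)))
        zo = sum(x[k] * p.W_o.data[k, j] for k in range(len(x)))
        zg = sum(x[k] * p.W_g.data[k, j] for k in range(len(x)))
        zi = sum(x[k] * p.W_i.data[k, j] for k in range(len(x)))
        for k in range(H):
            zf += h_prev[k] * p.U_f.data[k, j]
            zo += h_prev[k] * p.U_o.data[k, j]
            zg += h_prev[k] * p.U_g.data[k, j]
            zi += h_prev[k] * p.U_i.data[k, j]
        f[j] = sigmoid(zf + p.b_f.data[j])
        o[j] = sigmoid(zo + p.b_o.data[j])
        g[j] = math.tanh(zg + p.b_g.data[j])
        i_[j] = sigmoid(zi + p.b_i.data[j])
        c[j] = f[j] * c_prev[j] + i_[j] * g[j]
        h[j] = o[j] * math.tanh(c[j] if variant == "standard" else c_prev[j])
    return h, c


def attention_oracle(Q, K, V, scale):
    """Two-loop softmax(QK^T/scale)V."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        logits = np.array([np.dot(Q[i], K[j]) / scale for j in range(m)])
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        for j in range(m):
            out[i] += w[j] * V[j]
    return out


def multihead_oracle(X, p: AttentionParams):
    dh = p.head_dim
    scale = math.sqrt(p.d_model if p.scale_variant == "literal" else dh)
    heads = []
    for k in range(p.n_heads):
        Q = X @ p.W_Q[k].data
        K = X @ p.W_K[k].data
        V = X @ p.W_V[k].data
        heads.append(attention_oracle(Q, K, V, scale))
    return np.concatenate(heads, axis=1) @ p.W_O.data


def pool_oracle(H, p: PoolingParams):
    n = H.shape[0]
    scores = np.array([np.dot(np.tanh(H[t] @ p.W.data), p.v.data) for t in range(n)])
    e = np.exp(scores - scores.max())
    w = e / e.sum()
    return sum(w[t] * H[t] for t in range(n)), w


# ---------------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------------

class TestLSTMStep:
    def _zero_params(self, din, H):
        p = LSTMParams.create(np.random.default_rng(0), din, H)
        for t in vars(p).values():
            t.data[...] = 0.0
        return p

    @pytest.mark.parametrize("variant", ["standard", "literal"])
    def test_all_zero_inputs_give_half_gates_zero_state(self, variant):
        p = self._zero_params(3, 4)
        prev = LSTMState.zeros(1, 4)
        s = lstm_step(Tensor(np.zeros((1, 3))), prev, p, variant)
        np.testing.assert_allclose(s.f.data, 0.5)
        np.testing.assert_allclose(s.o.data, 0.5)
        np.testing.assert_allclose(s.i.data, 0.5)
        np.testing.assert_allclose(s.g.data, 0.0)
        np.testing.assert_allclose(s.c.data, 0.0)
        np.testing.assert_allclose(s.h.data, 0.0)

    def test_scalar_case_hand_computed(self):
        # 1-dim weights, only biases nonzero: b_i = b_f = 2, x irrelevant
        p = self._zero_params(1, 1)
        p.b_i.data[...] = 2.0
        p.b_f.data[...] = 2.0
        prev = LSTMState(h=Tensor(np.zeros((1, 1))), c=Tensor(np.full((1, 1), 0.7)))
        s = lstm_step(Tensor(np.zeros((1, 1))), prev, p)
        sig2 = sigmoid(2.0)
        c_expect = sig2 * 0.7 + sig2 * 0.0  # g = tanh(0) = 0
        np.testing.assert_allclose(s.c.data, c_expect, atol=1e-12)
        np.testing.assert_allclose(s.h.data, 0.5 * math.tanh(c_expect), atol=1e-12)

    def test_gate_ranges(self, rng):
        p = LSTMParams.create(rng, 5, 6)
        s = lstm_step(Tensor(rng.standard_normal((2, 5))), LSTMState.zeros(2, 6), p)
        for gate in (s.f, s.o, s.i):
            assert (gate.data > 0).all() and (gate.data < 1).all()
        assert (np.abs(s.g.data) < 1).all()

    def test_reference_hidden_width_concatenates_to_600(self, rng):
        p_f = LSTMParams.create(rng, 8, 300)
        p_b = LSTMParams.create(rng, 8, 300)
        X = Tensor(rng.standard_normal((1, 2, 8)))
        out = bilstm_encode(X, p_f, p_b, np.ones((1, 2), dtype=bool))
        assert out.shape == (1, 2, 600)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        din, H = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        variant = "standard" if trial % 2 == 0 else "literal"
        p = LSTMParams.create(rng, din, H)
        for t in vars(p).values():
            t.data[...] = rng.standard_normal(t.data.shape)
        x = rng.standard_normal(din)
        h0, c0 = rng.standard_normal(H), rng.standard_normal(H)
        prev = LSTMState(h=Tensor(h0[None]), c=Tensor(c0[None]))
        s = lstm_step(Tensor(x[None]), prev, p, variant)
        h_ref, c_ref = lstm_step_oracle(x, h0, c0, p, variant)
        np.testing.assert_allclose(s.h.data[0], h_ref, atol=1e-6)
        np.testing.assert_allclose(s.c.data[0], c_ref, atol=1e-6)

    def test_variants_agree_when_cell_is_stationary(self, rng):
        # force c_t == c_{t-1}: f = 1, i*g = 0 via huge b_f, tiny b_i
        p = LSTMParams.create(rng, 3, 4)
        p.b_f.data[...] = 50.0
        p.b_i.data[...] = -50.0
        prev = LSTMState(h=Tensor(rng.standard_normal((1, 4))),
                         c=Tensor(rng.standard_normal((1, 4))))
        x = Tensor(rng.standard_normal((1, 3)))
        s_std = lstm_step(x, prev, p, "standard")
        s_lit = lstm_step(x, prev, p, "literal")
        np.testing.assert_allclose(s_std.c.data, prev.c.data, atol=1e-9)
        np.testing.assert_allclose(s_std.h.data, s_lit.h.data, atol=1e-9)


class TestBiLSTM:
    def test_single_token_concatenates_two_single_steps(self, rng):
        p_f = LSTMParams.create(rng, 4, 3)
        p_b = LSTMParams.create(rng, 4, 3)
        x = rng.standard_normal((1, 1, 4))
        out = bilstm_encode(Tensor(x), p_f, p_b, np.ones((1, 1), dtype=bool))
        sf = lstm_step(Tensor(x[:, 0]), LSTMState.zeros(1, 3), p_f)
        sb = lstm_step(Tensor(x[:, 0]), LSTMState.zeros(1, 3), p_b)
        np.testing.assert_allclose(
            out.data[0, 0], np.concatenate([sf.h.data[0], sb.h.data[0]]), atol=1e-12)

    def test_palindrome_with_shared_params_is_mirror_symmetric(self, rng):
        p = LSTMParams.create(rng, 4, 3)
        half = rng.standard_normal((1, 2, 4))
        X = np.concatenate([half, half[:, ::-1]], axis=1)  # palindrome, n=4
        out = bilstm_encode(Tensor(X), p, p, np.ones((1, 4), dtype=bool)).data[0]
        H = 3
        for t in range(4):
            mirror = 4 - 1 - t
            np.testing.assert_allclose(out[t, :H], out[mirror, H:], atol=1e-10)

    def test_padding_does_not_change_real_rows(self, rng):
        p_f = LSTMParams.create(rng, 4, 3)
        p_b = LSTMParams.create(rng, 4, 3)
        X = rng.standard_normal((1, 3, 4))
        out_plain = bilstm_encode(Tensor(X), p_f, p_b,
                                  np.ones((1, 3), dtype=bool)).data
        Xpad = np.concatenate([X, rng.standard_normal((1, 2, 4))], axis=1)
        mask = np.array([[True, True, True, False, False]])
        out_pad = bilstm_encode(Tensor(Xpad), p_f, p_b, mask).data
        np.testing.assert_allclose(out_pad[:, :3], out_plain, atol=1e-12)
        np.testing.assert_allclose(out_pad[:, 3:], 0.0)

    def test_bad_mask_shape_rejected(self, rng):
        p = LSTMParams.create(rng, 4, 3)
        with pytest.raises(ValueError):
            bilstm_encode(Tensor(rng.standard_normal((1, 3, 4))), p, p,
                          np.ones((1, 5), dtype=bool))


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

class TestScaledDotAttention:
    def test_single_row_returns_value(self, rng):
        Q = Tensor(rng.standard_normal((1, 4)))
        V = Tensor(rng.standard_normal((1, 4)))
        out, w = scaled_dot_attention(Q, Q, V)
        np.testing.assert_allclose(out.data, V.data, atol=1e-12)
        np.testing.assert_allclose(w.data, 1.0)

    def test_zero_query_gives_column_means(self, rng):
        K = Tensor(rng.standard_normal((5, 4)))
        V = Tensor(rng.standard_normal((5, 3)))
        out, w = scaled_dot_attention(Tensor(np.zeros((2, 4))), K, V)
        np.testing.assert_allclose(out.data, np.tile(V.data.mean(0), (2, 1)), atol=1e-12)
        np.testing.assert_allclose(w.data, 1.0 / 5)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_two_loop_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n, m, d, dv = (int(rng.integers(1, 6)) for _ in range(4))
        Q = rng.standard_normal((n, d))
        K = rng.standard_normal((m, d))
        V = rng.standard_normal((m, dv))
        out, _ = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(V))
        np.testing.assert_allclose(out.data,
                                   attention_oracle(Q, K, V, math.sqrt(d)),
                                   atol=1e-6)

    def test_weights_rows_are_distributions_and_masked_zero(self, rng):
        X = Tensor(rng.standard_normal((1, 5, 4)))
        mask = np.array([[True, True, False, True, False]])
        _, w = scaled_dot_attention(X, X, X, mask=mask)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-12)
        assert (w.data >= 0).all()
        np.testing.assert_allclose(w.data[0, :, 2], 0.0)
        np.testing.assert_allclose(w.data[0, :, 4], 0.0)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(np.zeros((2, 3))),
                                 Tensor(np.zeros((2, 4))),
                                 Tensor(np.zeros((2, 4))))


class TestMultiheadAttention:
    def test_identity_single_head_reduces_to_plain_attention(self, rng):
        d = 4
        p = AttentionParams(
            W_Q=[Tensor(np.eye(d))], W_K=[Tensor(np.eye(d))],
            W_V=[Tensor(np.eye(d))], W_O=Tensor(np.eye(d)),
            n_heads=1, d_model=d)
        X = Tensor(rng.standard_normal((3, d)))
        out = multihead_attention(X, p)
        ref, _ = scaled_dot_attention(X, X, X, scale=math.sqrt(d))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)

    def test_reference_geometry_six_heads_of_width_100(self, rng):
        p = AttentionParams.create(rng, 600, 6)
        assert p.head_dim == 100
        assert p.W_Q[0].shape == (600, 100) and p.W_O.shape == (600, 600)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_per_head_loop_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        h = int(rng.integers(1, 4))
        d = h * int(rng.integers(1, 4))
        n = int(rng.integers(1, 6))
        p = AttentionParams.create(rng, d, h)
        X = rng.standard_normal((n, d))
        out = multihead_attention(Tensor(X), p)
        np.testing.assert_allclose(out.data, multihead_oracle(X, p), atol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionParams.create(rng, 10, 3)

    def test_permutation_equivariance(self, rng):
        p = AttentionParams.create(rng, 6, 2)
        X = rng.standard_normal((5, 6))
        perm = rng.permutation(5)
        out = multihead_attention(Tensor(X), p).data
        out_p = multihead_attention(Tensor(X[perm]), p).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestAttentionPool:
    def test_single_row_passthrough(self, rng):
        p = PoolingParams.create(rng, 4, 3)
        H = Tensor(rng.standard_normal((1, 4)))
        out, w = attention_pool(H, p)
        np.testing.assert_allclose(out.data, H.data[0], atol=1e-12)
        np.testing.assert_allclose(w.data, 1.0)

    def test_zero_score_vector_gives_mean_row(self, rng):
        p = PoolingParams.create(rng, 4, 3)
        p.v.data[...] = 0.0
        H = Tensor(rng.standard_normal((6, 4)))
        out, w = attention_pool(H, p)
        np.testing.assert_allclose(out.data, H.data.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(w.data, 1.0 / 6)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_loop_oracle(self, trial):
        rng = np.random.default_rng(4000 + trial)
        n, d = int(rng.integers(1, 7)), int(rng.integers(1, 5))
        p = PoolingParams.create(rng, d, int(rng.integers(1, 4)))
        H = rng.standard_normal((n, d))
        out, w = attention_pool(Tensor(H), p)
        ref_out, ref_w = pool_oracle(H, p)
        np.testing.assert_allclose(out.data, ref_out, atol=1e-6)
        np.testing.assert_allclose(w.data, ref_w, atol=1e-6)

    def test_output_in_convex_hull_and_weights_sum_to_one(self, rng):
        p = PoolingParams.create(rng, 3, 3)
        H = rng.standard_normal((1, 5, 3))
        mask = np.array([[True, True, True, False, False]])
        out, w = attention_pool(Tensor(H), p, mask)
        np.testing.assert_allclose(w.data.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(w.data[0, 3:], 0.0)
        lo = H[0, :3].min(axis=0) - 1e-9
        hi = H[0, :3].max(axis=0) + 1e-9
        assert ((out.data >= lo) & (out.data <= hi)).all()

    def test_fully_masked_sequence_rejected(self, rng):
        p = PoolingParams.create(rng, 3, 3)
        with pytest.raises(ValueError):
            attention_pool(Tensor(rng.standard_normal((1, 2, 3))), p,
                           np.zeros((1, 2), dtype=bool))


# ---------------------------------------------------------------------------
# Gradient checks per parameterized block
# ---------------------------------------------------------------------------

def _fd_check(params: dict, forward, tol=1e-4, samples=3):
    loss = forward()
    for p in params.values():
        p.grad = None
    loss.backward()
    rng = np.random.default_rng(0)
    for name, p in params.items():
        flat = p.data.reshape(-1)
        grad = (np.zeros_like(p.data) if p.grad is None else p.grad).reshape(-1)
        for i in rng.choice(flat.size, size=min(samples, flat.size), replace=False):
            old = flat[i]
            eps = 1e-6
            flat[i] = old + eps
            up = float(forward().data)
            flat[i] = old - eps
            down = float(forward().data)
            flat[i] = old
            fd = (up - down) / (2 * eps)
            denom = max(abs(fd) + abs(grad[i]), 1e-4)
            assert abs(fd - grad[i]) / denom < tol, f"{name}[{i}]: {fd} vs {grad[i]}"


class TestGradientChecks:
    def test_lstm_block(self, rng):
        p = LSTMParams.create(rng, 3, 4)
        x = Tensor(rng.standard_normal((2, 5, 3)))
        mask = np.ones((2, 5), dtype=bool)

        def forward():
            return (bilstm_encode(x, p, p, mask).tanh()).sum()

        _fd_check(p.named("lstm"), forward)

    def test_multihead_block(self, rng):
        p = AttentionParams.create(rng, 6, 2)
        X = Tensor(rng.standard_normal((4, 6)))

        def forward():
            return (multihead_attention(X, p) * multihead_attention(X, p)).sum()

        _fd_check(p.named("attn"), forward)

    def test_pooling_block(self, rng):
        p = PoolingParams.create(rng, 4, 3)
        H = Tensor(rng.standard_normal((5, 4)))

        def forward():
            out, _ = attention_pool(H, p)
            return (out * out).sum()

        _fd_check(p.named("pool"), forward)


# ---------------------------------------------------------------------------
# Full model forward
# ---------------------------------------------------------------------------

class TestModelForward:
    @pytest.fixture()
    def setup(self, small_corpus, tiny_model_config):
        ds = build_dataset(small_corpus.documents, small_corpus.mentions,
                           small_corpus.relations,
                           tiny_model_config.clip_distance)
        provider = pretrain_bilm(ds, tiny_model_config, seed=0)
        mc = tiny_model_config.model_config(provider.width, len(ds.pos_vocab))
        model = RelationModel(mc, np.random.default_rng(0))
        return ds, provider, model

    def test_probability_rows_sum_to_one(self, setup):
        ds, provider, model = setup
        batch = pad_batch(ds.instances[:8])
        log_p, _ = model.forward(batch, provider.batch_stacks(batch))
        np.testing.assert_allclose(np.exp(log_p.data).sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_output_layer_gives_uniform_probabilities(self, setup):
        ds, provider, model = setup
        model.W_out.data[...] = 0.0
        model.b_out.data[...] = 0.0
        batch = pad_batch(ds.instances[:4])
        log_p, _ = model.forward(batch, provider.batch_stacks(batch))
        probs = np.exp(log_p.data)
        entropy = -(probs * np.log(probs)).sum(axis=1)
        np.testing.assert_allclose(entropy, np.log(6), atol=1e-9)

    def test_eval_mode_deterministic_for_identical_instances(self, setup):
        ds, provider, model = setup
        inst = ds.instances[0]
        batch = pad_batch([inst, inst])
        log_p, _ = model.forward(batch, provider.batch_stacks(batch))
        np.testing.assert_allclose(log_p.data[0], log_p.data[1], atol=1e-12)

    def test_batch_size_invariance(self, setup):
        ds, provider, model = setup
        inst = ds.instances[3]
        solo = pad_batch([inst])
        log_solo, _ = model.forward(solo, provider.batch_stacks(solo))
        group = pad_batch(ds.instances[:32])
        log_group, _ = model.forward(group, provider.batch_stacks(group))
        np.testing.assert_allclose(log_solo.data[0], log_group.data[3], atol=1e-9)

    def test_perturbing_pad_token_ids_leaves_logits_unchanged(self, setup):
        ds, provider, model = setup
        by_len = sorted(ds.instances, key=len)
        batch = pad_batch([by_len[0], by_len[-1]])
        assert not batch.mask.all(), "need a genuinely padded batch"
        ref, _ = model.forward(batch, provider.batch_stacks(batch))
        batch.token_ids[~batch.mask] = 1  # scribble over PAD slots
        batch.pos_tag_ids[~batch.mask] = 1
        batch.dist_chem[~batch.mask] = 2
        batch.dist_gene[~batch.mask] = 2
        out, _ = model.forward(batch, provider.batch_stacks(batch))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)

    def test_inconsistent_heads_rejected_at_construction(self):
        cfg = ModelConfig(context_dim=8, pos_vocab_size=5, hidden_size=5,
                          n_heads=4, pos_emb_dim=3, position_emb_dim=3)
        with pytest.raises(ValueError):
            RelationModel(cfg)
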