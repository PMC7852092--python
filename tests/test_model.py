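"""The dual-attention network against straight-line reference arithmetic.

Every attention/recurrence formula is re-evaluated here with plain Python
loops (no vectorisation, no shared code with the package) and compared to
the module implementations on random small instances.
"""

import math

import numpy as np
import pytest

from attnbind import autodiff as ad
from attnbind.autodiff import Tensor
from attnbind.model import (
    DualAttentionModel,
    LSTMParams,
    LSTMState,
    ModelConfig,
    PairwiseAttentionParams,
    SingleAttentionParams,
    bce_loss,
    bilstm,
    lstm_step,
    pairwise_attention,
    positional_encoding,
    single_attention,
)

# ---------------------------------------------------------------------------
# straight-line oracles
# ---------------------------------------------------------------------------

def _sig(z):
    return 1.0 / (1.0 + math.exp(-z))


def _matvec(W, v, b):
    return [sum(W[i][j] * v[j] for j in range(len(v))) + b[i] for i in range(len(W))]


def oracle_lstm_step(h, c, x, p: LSTMParams):
    hx = list(h) + list(x)
    f = [_sig(z) for z in _matvec(p.W_f, hx, p.b_f)]
    i = [_sig(z) for z in _matvec(p.W_i, hx, p.b_i)]
    ctil = [math.tanh(z) for z in _matvec(p.W_C, hx, p.b_C)]
    o = [_sig(z) for z in _matvec(p.W_o, hx, p.b_o)]
    c_new = [f[k] * c[k] + i[k] * ctil[k] for k in range(len(c))]
    h_new = [o[k] * math.tanh(c_new[k]) for k in range(len(c))]
    return h_new, c_new


def oracle_single_attention(h, M, bias):
    l, r = len(h), len(h[0])
    e = [
        [sum(M[i][k] * h[k][j] for k in range(l)) + bias[i][j] for j in range(r)]
        for i in range(l)
    ]
    alpha = [[0.0] * r for _ in range(l)]
    for j in range(r):
        mx = max(e[i][j] for i in range(l))
        denom = sum(math.exp(e[i][j] - mx) for i in range(l))
        for i in range(l):
            alpha[i][j] = math.exp(e[i][j] - mx) / denom
    alpha_bar = [sum(alpha[i][j] for j in range(r)) / r for i in range(l)]
    z = [[h[i][j] * alpha_bar[i] for j in range(r)] for i in range(l)]
    return z, alpha_bar


def oracle_pairwise_attention(h, Wq, Wk, Wv, dk):
    l, c = len(h), len(h[0])

    def proj(W):
        cols = len(W[0])
        return [
            [sum(h[i][m] * W[m][j] for m in range(c)) for j in range(cols)]
            for i in range(l)
        ]

    Q, K, V = proj(Wq), proj(Wk), proj(Wv)
    logits = [
        [sum(Q[i][m] * K[j][m] for m in range(len(Q[0]))) / math.sqrt(dk)
         for j in range(l)]
        for i in range(l)
    ]
    attn = []
    for row in logits:
        mx = max(row)
        exps = [math.exp(v - mx) for v in row]
        s = sum(exps)
        attn.append([v / s for v in exps])
    Z = [
        [sum(attn[i][j] * V[j][m] for j in range(l)) for m in range(len(V[0]))]
        for i in range(l)
    ]
    return Z, attn


def oracle_positional_encoding(L, d):
    table = [[0.0] * d for _ in range(L)]
    for pos in range(L):
        for j in range(d):
            angle = pos / (10000.0 ** (2 * (j // 2) / d))
            table[pos][j] = math.sin(angle) if j % 2 == 0 else math.cos(angle)
    return table


def random_lstm_params(rng, hidden, inputs):
    def w():
        return rng.standard_normal((hidden, hidden + inputs))

    def b():
        return rng.standard_normal(hidden)

    return LSTMParams(w(), w(), w(), w(), b(), b(), b(), b())


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestLSTM:
    def test_zero_parameters_fix_hidden_state_at_zero(self):
        p = LSTMParams(*[np.zeros((2, 5))] * 4, *[np.zeros(2)] * 4)
        state = lstm_step(LSTMState(np.zeros(2), np.zeros(2)), np.ones(3), p)
        assert np.allclose(state.h, 0.0)

    def test_scalar_hand_evaluation(self):
        b_C = 5.0
        p = LSTMParams(*[np.zeros((1, 2))] * 4,
                       np.zeros(1), np.zeros(1), np.array([b_C]), np.zeros(1))
        state = lstm_step(LSTMState(np.zeros(1), np.zeros(1)), np.array([0.7]), p)
        expected = 0.5 * math.tanh(0.5 * math.tanh(b_C))
        assert state.h[0] == pytest.approx(expected, abs=1e-12)

    def test_hidden_state_bounded(self, rng):
        p = random_lstm_params(rng, 4, 3)
        state = LSTMState(np.zeros(4), np.zeros(4))
        for _ in range(20):
            state = lstm_step(state, rng.standard_normal(3) * 50, p)
            assert np.all(np.abs(state.h) <= 1.0)

    def test_against_straight_line_oracle(self, rng):
        for _ in range(25):
            p = random_lstm_params(rng, 3, 2)
            h0, c0 = rng.standard_normal(3), rng.standard_normal(3)
            x = rng.standard_normal(2)
            state = lstm_step(LSTMState(h0, c0), x, p)
            oh, oc = oracle_lstm_step(h0.tolist(), c0.tolist(), x.tolist(), p)
            assert np.allclose(state.h, oh, atol=1e-6)
            assert np.allclose(state.c, oc, atol=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        p = random_lstm_params(rng, 3, 2)
        with pytest.raises(ValueError):
            lstm_step(LSTMState(np.zeros(3), np.zeros(3)), np.zeros(5), p)


class TestBiLSTM:
    def test_output_width_doubles_hidden(self, rng):
        fwd = random_lstm_params(rng, 32, 4)
        bwd = random_lstm_params(rng, 32, 4)
        out = bilstm(rng.standard_normal((6, 4)), fwd, bwd)
        assert out.shape == (6, 64)

    def test_direction_symmetry_under_sequence_reversal(self, rng):
        fwd = random_lstm_params(rng, 3, 2)
        bwd = random_lstm_params(rng, 3, 2)
        seq = rng.standard_normal((7, 2))
        out = bilstm(seq, fwd, bwd)
        flipped = bilstm(seq[::-1], bwd, fwd)
        assert np.allclose(out[:, :3], flipped[::-1, 3:], atol=1e-12)
        assert np.allclose(out[:, 3:], flipped[::-1, :3], atol=1e-12)

    def test_empty_sequence(self, rng):
        fwd = random_lstm_params(rng, 3, 2)
        out = bilstm(np.zeros((0, 2)), fwd, fwd)
        assert out.shape == (0, 6)


class TestSingleAttention:
    def test_weights_sum_to_one(self, rng):
        h = rng.standard_normal((5, 3))
        p = SingleAttentionParams(rng.standard_normal((5, 5)),
                                  rng.standard_normal((5, 3)))
        _, alpha_bar = single_attention(h, p)
        assert np.sum(alpha_bar) == pytest.approx(1.0, abs=1e-9)

    def test_two_position_hand_example(self):
        h = np.array([[1.0], [0.0]])
        p = SingleAttentionParams(np.eye(2), np.zeros((2, 1)))
        z, alpha_bar = single_attention(h, p)
        e = math.e
        assert alpha_bar == pytest.approx([e / (e + 1), 1 / (e + 1)], abs=1e-4)
        assert z[:, 0] == pytest.approx([e / (e + 1), 0.0], abs=1e-4)

    def test_column_constant_scores_give_uniform_weights(self, rng):
        # h equal within each column and M with equal row sums makes M.h
        # column-constant, so the softmax over positions must be uniform
        h = np.ones((6, 4)) * rng.standard_normal(4)
        M = rng.standard_normal((6, 6))
        M = M - M.mean(axis=1, keepdims=True) + 1.0 / 6  # row sums all 1
        p = SingleAttentionParams(M, np.zeros((6, 4)))
        _, alpha_bar = single_attention(h, p)
        assert np.allclose(alpha_bar, 1 / 6)

    def test_against_straight_line_oracle(self, rng):
        for _ in range(25):
            h = rng.standard_normal((4, 3))
            p = SingleAttentionParams(rng.standard_normal((4, 4)),
                                      rng.standard_normal((4, 3)))
            z, alpha_bar = single_attention(h, p)
            oz, oa = oracle_single_attention(h.tolist(), p.M.tolist(), p.bias.tolist())
            assert np.allclose(alpha_bar, oa, atol=1e-6)
            assert np.allclose(z, oz, atol=1e-6)

    def test_nonfinite_input_rejected(self, rng):
        p = SingleAttentionParams(np.eye(2), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            single_attention(np.array([[np.nan], [0.0]]), p)


class TestPairwiseAttention:
    def test_rows_are_stochastic(self, rng):
        h = rng.standard_normal((6, 4))
        p = PairwiseAttentionParams(*(rng.standard_normal((4, 3)) for _ in range(3)))
        _, attn = pairwise_attention(h, p)
        assert np.allclose(attn.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_query_key_gives_uniform_attention(self, rng):
        h = rng.standard_normal((5, 4))
        p = PairwiseAttentionParams(np.zeros((4, 3)), np.zeros((4, 3)),
                                    rng.standard_normal((4, 2)))
        Z, attn = pairwise_attention(h, p)
        assert np.allclose(attn, 1 / 5)
        assert np.allclose(Z, np.tile((h @ p.W_V).mean(axis=0), (5, 1)))

    def test_default_dimensions_are_64(self):
        cfg = ModelConfig()
        assert cfg.attention_dk == 64 and cfg.attention_dv == 64

    def test_against_straight_line_oracle(self, rng):
        for _ in range(25):
            h = rng.standard_normal((4, 3))
            p = PairwiseAttentionParams(*(rng.standard_normal((3, 2)) for _ in range(3)))
            Z, attn = pairwise_attention(h, p)
            oZ, oattn = oracle_pairwise_attention(
                h.tolist(), p.W_Q.tolist(), p.W_K.tolist(), p.W_V.tolist(), p.d_k
            )
            assert np.allclose(attn, oattn, atol=1e-6)
            assert np.allclose(Z, oZ, atol=1e-6)


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        table = positional_encoding(4, 6)
        assert np.allclose(table[0, 0::2], 0.0)
        assert np.allclose(table[0, 1::2], 1.0)

    def test_first_column_is_plain_sine(self):
        for d in (4, 10, 64):
            assert positional_encoding(3, d)[1, 0] == pytest.approx(math.sin(1.0))

    def test_matches_oracle(self):
        table = positional_encoding(7, 6)
        assert np.allclose(table, oracle_positional_encoding(7, 6), atol=1e-12)

    def test_fixed_offset_rows_are_rotations(self):
        # PE(pos+k) must be a position-independent linear combination of
        # PE(pos): for each frequency pair it is a rotation by k*omega_i.
        L, d = 40, 8
        table = positional_encoding(L, d)
        for k in (1, 5, 17):
            for i in range(d // 2):
                w = 1.0 / (10000.0 ** (2 * i / d))
                c, s = math.cos(k * w), math.sin(k * w)
                sin_part = table[: L - k, 2 * i] * c + table[: L - k, 2 * i + 1] * s
                cos_part = table[: L - k, 2 * i + 1] * c - table[: L - k, 2 * i] * s
                assert np.allclose(sin_part, table[k:, 2 * i], atol=1e-9)
                assert np.allclose(cos_part, table[k:, 2 * i + 1], atol=1e-9)


def tiny_config(**overrides):
    base = dict(bin_size=40, flank=30, conv_filters=4, conv_width=6,
                pool_size=5, lstm_units=3, attention_dk=4, attention_dv=4,
                dense_units=5, dropout=0.0, seed=11)
    base.update(overrides)
    return ModelConfig(**base)


def random_inputs(cfg, rng, batch=3):
    xf = rng.random((batch, cfg.seq_length, cfg.n_channels))
    xr = xf[:, ::-1, :][:, :, [3, 2, 1, 0, 4, 5]]
    ns = rng.random((batch, 14))
    return xf, xr, ns


class TestFullModel:
    def test_scores_strictly_inside_unit_interval(self, rng):
        cfg = tiny_config()
        model = DualAttentionModel(cfg)
        xf, xr, ns = random_inputs(cfg, rng)
        s = model.forward(xf, xr, ns).data
        assert np.all((s > 0) & (s < 1))

    def test_strand_swap_invariance_with_mean_merge(self, rng):
        cfg = tiny_config()
        model = DualAttentionModel(cfg)
        xf, xr, ns = random_inputs(cfg, rng)
        a = model.forward(xf, xr, ns).data
        b = model.forward(xr, xf, ns).data
        assert np.allclose(a, b, atol=1e-12)

    def test_branch_merge_mean(self):
        model = DualAttentionModel(tiny_config())
        merged = model._merge(Tensor(np.array([0.4])), Tensor(np.array([0.6])), "mean")
        assert merged.data[0] == pytest.approx(0.5)

    def test_forward_is_deterministic_at_inference(self, rng):
        cfg = tiny_config(dropout=0.3)
        model = DualAttentionModel(cfg)
        xf, xr, ns = random_inputs(cfg, rng)
        assert np.array_equal(
            model.forward(xf, xr, ns).data, model.forward(xf, xr, ns).data
        )

    def test_gradient_check_through_both_attention_branches(self, rng):
        cfg = tiny_config()
        model = DualAttentionModel(cfg)
        xf, xr, ns = random_inputs(cfg, rng, batch=2)
        y = np.array([1.0, 0.0])
        loss = bce_loss(model.forward(xf, xr, ns), y)
        for p in model.params.values():
            p.grad = None
        loss.backward()

        def loss_val():
            with ad.no_grad():
                return float(bce_loss(model.forward(xf, xr, ns), y).data)

        eps = 1e-6
        rng2 = np.random.default_rng(5)
        for name in ("conv_w", "att_M", "att_bias", "Wq", "Wk", "Wv",
                     "lstm_fwd_W", "lstm_bwd_b", "single_W1", "pair_W2"):
            t = model.params[name]
            flat = t.data.reshape(-1)
            for idx in rng2.choice(flat.size, size=3, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_val()
                flat[idx] = orig - eps
                lo = loss_val()
                flat[idx] = orig
                fd = (hi - lo) / (2 * eps)
                bp = t.grad.reshape(-1)[idx]
                assert bp == pytest.approx(fd, abs=1e-4), name

    def test_wrong_input_shape_rejected(self, rng):
        cfg = tiny_config()
        model = DualAttentionModel(cfg)
        bad = rng.random((2, cfg.seq_length + 1, cfg.n_channels))
        with pytest.raises(ValueError):
            model.forward(bad, bad, rng.random((2, 14)))


class TestConfigAndCheckpoint:
    def test_defaults_match_published_setup(self):
        cfg = ModelConfig()
        assert cfg.seq_length == 1000
        assert cfg.bin_size == 200 and cfg.flank == 400
        assert cfg.epochs == 60 and cfg.patience == 5
        assert cfg.merge_modules == "mean"

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(learning_rate=0.007, merge_strands="max")
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert ModelConfig.from_yaml(path) == cfg

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = tiny_config()
        model = DualAttentionModel(cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = DualAttentionModel.load(path)
        assert loaded.config == cfg
        xf, xr, ns = random_inputs(cfg, rng)
        assert np.array_equal(
            model.forward(xf, xr, ns).data, loaded.forward(xf, xr, ns).data
        )
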