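"""The dual-attention binding-prediction network.

Architecture (per strand, weights shared between strands — a Siamese
layout): 1-D convolution + ReLU -> max-pooling -> Bi-LSTM -> two parallel
attention branches.  The *single attention* branch learns one normalized
weight per sequence position and reweights the Bi-LSTM features with it;
the *pairwise attention* branch is scaled dot-product attention
(softmax(Q K^T / sqrt(d_k)) V) over sinusoidally position-encoded
features.  Each branch flattens its output, fuses the length-14
non-sequential vector, and scores the region through a dense + sigmoid
head.  Strand scores are merged first (default mean), then the two branch
scores (default mean).

The module exposes both plain-NumPy functional operations (``lstm_step``,
``bilstm``, ``single_attention``, ``pairwise_attention``,
``positional_encoding``) and the trainable :class:`DualAttentionModel`
built on the autodiff tape; the two share the same arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Every tunable the network and training loop consume.

    ``seq_length`` is derived: bin_size + 2*flank (defaults 200 + 2*400 =
    1000 bp).  All fields round-trip through a flat YAML document.
    """

    bin_size: int = 200
    flank: int = 400
    use_conservation: bool = False
    use_cgi: bool = False
    conv_filters: int = 64
    conv_width: int = 34
    pool_size: int = 10
    lstm_units: int = 32
    attention_dk: int = 64
    attention_dv: int = 64
    dense_units: int = 64
    dropout: float = 0.1
    learning_rate: float = 1e-3
    merge_strands: Literal["mean", "max"] = "mean"
    merge_modules: Literal["mean", "max"] = "mean"
    negative_ratio: float = 1.0
    balance_loss: bool = True  # weight positives by negative_ratio in the BCE
    positive_mode: Literal["all_positives", "peak_resample"] = "all_positives"
    epochs: int = 60
    patience: int = 5
    patience_tol: float = 1e-5
    batch_size: int = 32
    seed: int = 0

    @property
    def seq_length(self) -> int:
        return self.bin_size + 2 * self.flank

    @property
    def n_channels(self) -> int:
        return 6 + int(self.use_conservation) + int(self.use_cgi)

    @property
    def n_attention_positions(self) -> int:
        return (self.seq_length - self.conv_width + 1) // self.pool_size

    @property
    def downsample_factor(self) -> int:
        """bp of input per attention position (conv stride 1, pool stride p)."""
        return self.pool_size

    @property
    def attention_offset(self) -> int:
        """Center of attention position 0's receptive field, in input bp."""
        return (self.pool_size + self.conv_width - 2) // 2

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# functional building blocks (plain NumPy)
# ---------------------------------------------------------------------------

def _np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _np_softmax(x, axis):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class LSTMParams:
    """Gate weights of one LSTM direction; each W_* maps [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


def lstm_step(state: LSTMState, x_t: np.ndarray, p: LSTMParams) -> LSTMState:
    """One LSTM recurrence: gated update of cell and hidden state.

    f_t, i_t, o_t are sigmoid gates over the concatenated [h_{t-1}, x_t];
    the candidate cell state uses tanh; C_t = f*C_{t-1} + i*C~; h_t =
    o * tanh(C_t).
    """
    hx = np.concatenate([state.h, x_t])
    if hx.shape[0] != p.W_f.shape[1]:
        raise ValueError(
            f"gate weights expect input of length {p.W_f.shape[1]}, got {hx.shape[0]}"
        )
    f = _np_sigmoid(p.W_f @ hx + p.b_f)
    i = _np_sigmoid(p.W_i @ hx + p.b_i)
    c_tilde = np.tanh(p.W_C @ hx + p.b_C)
    c = f * state.c + i * c_tilde
    o = _np_sigmoid(p.W_o @ hx + p.b_o)
    return LSTMState(h=o * np.tanh(c), c=c)


def lstm_run(seq: np.ndarray, p: LSTMParams) -> np.ndarray:
    """Run an LSTM over (L, c) input, returning (L, hidden) hidden states."""
    r = p.hidden_size
    state = LSTMState(np.zeros(r), np.zeros(r))
    out = np.zeros((seq.shape[0], r))
    for t in range(seq.shape[0]):
        state = lstm_step(state, seq[t], p)
        out[t] = state.h
    return out


def bilstm(seq: np.ndarray, fwd: LSTMParams, bwd: LSTMParams) -> np.ndarray:
    """Bidirectional LSTM: forward and reversed passes concatenated on the
    feature axis, so the output width is twice the hidden size."""
    h_f = lstm_run(seq, fwd)
    h_b = lstm_run(seq[::-1], bwd)[::-1]
    return np.concatenate([h_f, h_b], axis=1)


@dataclass
class SingleAttentionParams:
    M: np.ndarray  # (l, l) position-mixing weights
    bias: np.ndarray  # (l, r)


def single_attention(
    h: np.ndarray, p: SingleAttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Position-wise attention: e = M h + bias, softmax over positions per
    feature column, averaged across columns to one weight per position,
    which rescales the input.  Returns (z, alpha_bar)."""
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite attention input")
    e = p.M @ h + p.bias
    alpha = _np_softmax(e, axis=0)
    alpha_bar = alpha.mean(axis=1)
    z = h * alpha_bar[:, None]
    return z, alpha_bar


@dataclass
class PairwiseAttentionParams:
    W_Q: np.ndarray  # (c, d_k)
    W_K: np.ndarray  # (c, d_k)
    W_V: np.ndarray  # (c, d_v)

    @property
    def d_k(self) -> int:
        return self.W_Q.shape[1]

    @property
    def d_v(self) -> int:
        return self.W_V.shape[1]


def pairwise_attention(
    h_pe: np.ndarray, p: PairwiseAttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention: Z = softmax(Q K^T / sqrt(d_k)) V.

    ``h_pe`` must already include positional encodings.  Returns (Z,
    attention matrix); the attention matrix is row-stochastic.
    """
    Q = h_pe @ p.W_Q
    K = h_pe @ p.W_K
    V = h_pe @ p.W_V
    attn = _np_softmax(Q @ K.T / np.sqrt(p.d_k), axis=1)
    return attn @ V, attn


def positional_encoding(L: int, d: int) -> np.ndarray:
    """Sinusoidal positional-encoding table: sin at even columns, cos at
    odd columns, with frequency 1/10000^(2i/d) for column pair i."""
    table = np.zeros((L, d))
    pos = np.arange(L)[:, None]
    j = np.arange(d)
    i = j // 2
    angle = pos / np.power(10000.0, 2.0 * i / d)
    table[:, 0::2] = np.sin(angle[:, 0::2])
    if d > 1:
        table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


# ---------------------------------------------------------------------------
# the trainable network
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


@dataclass
class AttentionTrace:
    """Per-position attention weights of one branch on one strand,
    mappable back to genome coordinates via (origin, downsample_factor)."""

    weights: np.ndarray  # (l,) alpha_bar or pairwise column sums
    branch: Literal["single", "pairwise"]
    strand: Literal["forward", "reverse_complement"]
    downsample_factor: int = 1
    origin: int = 0
    matrix: np.ndarray | None = None  # (l, l) pairwise attention, optional

    def position_to_genomic(self, pos: int) -> int:
        return self.origin + pos * self.downsample_factor


class DualAttentionModel:
    """Siamese dual-attention network on the autodiff substrate."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._built = False
        self.build()

    # -- parameters ---------------------------------------------------------

    def build(self) -> None:
        c = self.config
        rng = np.random.default_rng(c.seed)
        P: dict[str, np.ndarray] = {}
        ch = c.n_channels
        P["conv_w"] = _glorot(rng, (c.conv_width, ch, c.conv_filters))
        P["conv_b"] = np.zeros(c.conv_filters)
        r = c.lstm_units
        for d in ("fwd", "bwd"):
            P[f"lstm_{d}_W"] = _glorot(rng, (r + c.conv_filters, 4 * r))
            b = np.zeros(4 * r)
            b[:r] = 1.0  # forget-gate bias
            P[f"lstm_{d}_b"] = b
        l = c.n_attention_positions
        width = 2 * r
        # identity + noise: the position-mixing matrix starts out passing
        # each position's own features through, so early attention reflects
        # local content rather than an arbitrary fixed mixture
        P["att_M"] = np.eye(l) + _glorot(rng, (l, l)) * 0.1
        P["att_bias"] = np.zeros((l, width))
        P["Wq"] = _glorot(rng, (width, c.attention_dk))
        P["Wk"] = _glorot(rng, (width, c.attention_dk))
        P["Wv"] = _glorot(rng, (width, c.attention_dv))
        nonseq = 14
        P["single_W1"] = _glorot(rng, (l * width + nonseq, c.dense_units))
        P["single_b1"] = np.zeros(c.dense_units)
        P["single_W2"] = _glorot(rng, (c.dense_units, 1))
        P["single_b2"] = np.zeros(1)
        P["pair_W1"] = _glorot(rng, (l * c.attention_dv + nonseq, c.dense_units))
        P["pair_b1"] = np.zeros(c.dense_units)
        P["pair_W2"] = _glorot(rng, (c.dense_units, 1))
        P["pair_b2"] = np.zeros(1)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in P.items()}
        self._pe = positional_encoding(l, width)
        self._built = True

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = weights[k].copy()

    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the embedded config."""
        cfg = json.dumps(dataclasses.asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **self.get_weights())

    @classmethod
    def load(cls, path) -> "DualAttentionModel":
        with np.load(path) as npz:
            cfg = json.loads(bytes(npz["__config__"]).decode())
            model = cls(ModelConfig(**cfg))
            model.set_weights({k: npz[k] for k in npz.files if k != "__config__"})
        return model

    # -- forward ------------------------------------------------------------

    def _trunk(self, x: Tensor) -> Tensor:
        c = self.config
        conv = ad.relu(ad.conv1d(x, self.params["conv_w"], self.params["conv_b"]))
        pooled = ad.maxpool1d(conv, c.pool_size)
        return self._bilstm(pooled)

    def _lstm_direction(self, x: Tensor, name: str) -> list[Tensor]:
        c = self.config
        r = c.lstm_units
        B, L, _ = x.shape
        W, b = self.params[f"lstm_{name}_W"], self.params[f"lstm_{name}_b"]
        h = Tensor(np.zeros((B, r)))
        cstate = Tensor(np.zeros((B, r)))
        outs = []
        for t in range(L):
            xt = ad.getitem(x, (slice(None), t, slice(None)))
            z = ad.add(ad.matmul(ad.concat([h, xt], axis=1), W), b)
            f = ad.sigmoid(ad.getitem(z, (slice(None), slice(0, r))))
            i = ad.sigmoid(ad.getitem(z, (slice(None), slice(r, 2 * r))))
            g = ad.tanh(ad.getitem(z, (slice(None), slice(2 * r, 3 * r))))
            o = ad.sigmoid(ad.getitem(z, (slice(None), slice(3 * r, 4 * r))))
            cstate = ad.add(ad.mul(f, cstate), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(cstate))
            outs.append(ad.reshape(h, (B, 1, r)))
        return outs

    def _bilstm(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        fwd = self._lstm_direction(x, "fwd")
        rev_in = ad.getitem(x, (slice(None), slice(None, None, -1), slice(None)))
        bwd = self._lstm_direction(rev_in, "bwd")[::-1]
        h_f = ad.concat(fwd, axis=1)
        h_b = ad.concat(bwd, axis=1)
        return ad.concat([h_f, h_b], axis=2)

    def _head(self, flat: Tensor, nonseq: Tensor, prefix: str,
              train: bool, rng) -> Tensor:
        c = self.config
        x = ad.concat([flat, nonseq], axis=1)
        if train and c.dropout > 0:
            x = ad.dropout(x, c.dropout, rng)
        hid = ad.relu(ad.add(ad.matmul(x, self.params[f"{prefix}_W1"]),
                             self.params[f"{prefix}_b1"]))
        out = ad.sigmoid(ad.add(ad.matmul(hid, self.params[f"{prefix}_W2"]),
                                self.params[f"{prefix}_b2"]))
        return ad.reshape(out, (out.shape[0],))

    def _branch_single(self, h: Tensor, nonseq: Tensor, train: bool, rng):
        B, l, w = h.shape
        e = ad.add(ad.matmul(self.params["att_M"], h), self.params["att_bias"])
        alpha = ad.softmax(e, axis=1)
        alpha_bar = ad.tmean(alpha, axis=2)  # (B, l)
        z = ad.mul(h, ad.reshape(alpha_bar, (B, l, 1)))
        score = self._head(ad.reshape(z, (B, l * w)), nonseq, "single", train, rng)
        return score, alpha_bar.data

    def _branch_pair(self, h: Tensor, nonseq: Tensor, train: bool, rng):
        c = self.config
        B, l, w = h.shape
        hp = ad.add(h, Tensor(self._pe))
        Q = ad.matmul(hp, self.params["Wq"])
        K = ad.matmul(hp, self.params["Wk"])
        V = ad.matmul(hp, self.params["Wv"])
        logits = ad.scale(ad.matmul(Q, ad.transpose(K, (0, 2, 1))),
                          1.0 / np.sqrt(c.attention_dk))
        attn = ad.softmax(logits, axis=2)
        Z = ad.matmul(attn, V)
        score = self._head(ad.reshape(Z, (B, l * c.attention_dv)), nonseq,
                           "pair", train, rng)
        return score, attn.data

    def _merge(self, a: Tensor, b: Tensor, how: str) -> Tensor:
        if how == "mean":
            return ad.scale(ad.add(a, b), 0.5)
        if how == "max":
            return ad.maximum(a, b)
        raise ValueError(f"unknown merge {how!r}")

    def forward(
        self,
        block_fwd: np.ndarray | Tensor,
        block_rc: np.ndarray | Tensor,
        nonseq: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_traces: bool = False,
        return_matrices: bool = False,
    ):
        """Score a batch of region pairs.

        ``block_fwd``/``block_rc`` are (B, L, C); ``nonseq`` is (B, 14).
        Returns the merged score Tensor (B,), and optionally the attention
        traces per (branch, strand).
        """
        if not self._built:
            raise RuntimeError("model is not built")
        c = self.config
        if rng is None:
            rng = np.random.default_rng(c.seed)
        xf = block_fwd if isinstance(block_fwd, Tensor) else Tensor(block_fwd)
        xr = block_rc if isinstance(block_rc, Tensor) else Tensor(block_rc)
        if xf.shape != xr.shape:
            raise ValueError("strand blocks must share a shape")
        if xf.shape[1] != c.seq_length or xf.shape[2] != c.n_channels:
            raise ValueError(
                f"expected blocks of shape (B, {c.seq_length}, {c.n_channels}), "
                f"got {xf.shape}"
            )
        ns = Tensor(np.asarray(nonseq, dtype=np.float64))
        traces: dict[tuple[str, str], AttentionTrace] = {}
        strand_scores: dict[str, dict[str, Tensor]] = {"single": {}, "pairwise": {}}
        for strand, x in (("forward", xf), ("reverse_complement", xr)):
            h = self._trunk(x)
            s_single, alpha = self._branch_single(h, ns, train, rng)
            s_pair, attn = self._branch_pair(h, ns, train, rng)
            strand_scores["single"][strand] = s_single
            strand_scores["pairwise"][strand] = s_pair
            if return_traces:
                traces[("single", strand)] = AttentionTrace(
                    alpha, "single", strand, c.downsample_factor,
                )
                traces[("pairwise", strand)] = AttentionTrace(
                    attn.sum(axis=1), "pairwise", strand, c.downsample_factor,
                    matrix=attn if return_matrices else None,
                )
        branch_scores = {
            br: self._merge(d["forward"], d["reverse_complement"], c.merge_strands)
            for br, d in strand_scores.items()
        }
        final = self._merge(branch_scores["single"], branch_scores["pairwise"],
                            c.merge_modules)
        if return_traces:
            return final, traces
        return final

    def predict(
        self, block_fwd, block_rc, nonseq, batch_size: int | None = None
    ) -> np.ndarray:
        """Inference scores, dropout off, tape disabled, minibatched."""
        bs = batch_size or self.config.batch_size
        n = block_fwd.shape[0]
        out = np.zeros(n)
        with ad.no_grad():
            for lo in range(0, n, bs):
                hi = min(lo + bs, n)
                out[lo:hi] = self.forward(
                    block_fwd[lo:hi], block_rc[lo:hi], nonseq[lo:hi]
                ).data
        return out


def bce_loss(
    scores: Tensor, labels: np.ndarray, eps: float = 1e-12,
    pos_weight: float = 1.0,
) -> Tensor:
    """Binary cross-entropy, averaged over the batch.

    ``pos_weight`` rescales the positive-class term; setting it to the
    negative:positive sampling ratio keeps the model calibrated to a
    balanced prior while each epoch still covers ``ratio`` times more
    negatives.
    """
    y = np.asarray(labels, dtype=np.float64)
    term_pos = ad.mul(Tensor(pos_weight * y), ad.log(scores, eps))
    term_neg = ad.mul(Tensor(1.0 - y), ad.log(ad.sub(1.0, scores), eps))
    return ad.scale(ad.tmean(ad.add(term_pos, term_neg)), -1.0)
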