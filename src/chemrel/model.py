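"""The relation classifier network.

Architecture, bottom to top:

1. per-token input vector = contextual representation (from the
   bidirectional language model, mixed ELMo-style) concatenated with two
   position embeddings (distance to the chemical and to the gene
   mention) and a POS-tag embedding;
2. a bidirectional LSTM over the sentence, forward and backward hidden
   states concatenated per token (width 2H);
3. multihead scaled dot-product self-attention over the Bi-LSTM output;
4. attention pooling to a single sentence vector (scores
   ``a_t = v^T tanh(W h_t)``, softmax over unmasked positions);
5. a softmax layer over the six labels (NEG + five evaluated CPR
   classes).

The LSTM cell follows the classic gate equations

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)      (forget gate)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)      (output gate)
    g_t = tanh   (W_g x_t + U_g h_{t-1} + b_g)      (candidate)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)      (input gate)
    c_t = f_t * c_{t-1} + i_t * g_t

with ``h_t = o_t * tanh(c_t)`` in the default ``standard`` variant.  A
``literal`` variant with ``h_t = o_t * tanh(c_{t-1})`` is kept behind a
flag for fidelity experiments; both coincide whenever c_t == c_{t-1}.

Attention is ``softmax(Q K^T / scale) V`` per head with per-head linear
projections and a final output projection; padded key positions receive
an additive -1e30 logit so their weight underflows to exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, stack
from .features import Batch

NEG_INF = -1e30


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Gate weights: W_* input->hidden, U_* recurrent, b_* biases."""

    W_f: Tensor
    W_o: Tensor
    W_g: Tensor
    W_i: Tensor
    U_f: Tensor
    U_o: Tensor
    U_g: Tensor
    U_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_g: Tensor
    b_i: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, input_dim: int, hidden: int) -> "LSTMParams":
        def w():
            return Tensor(glorot(rng, input_dim, hidden), requires_grad=True)

        def u():
            return Tensor(glorot(rng, hidden, hidden), requires_grad=True)

        def b():
            return Tensor(np.zeros(hidden), requires_grad=True)

        # forget-gate bias starts at 1 (the usual trick to open the
        # memory path early in training)
        return cls(w(), w(), w(), w(), u(), u(), u(), u(),
                   Tensor(np.ones(hidden), requires_grad=True), b(), b(), b())

    @property
    def hidden_size(self) -> int:
        return self.b_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[0]

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.{k}": v for k, v in vars(self).items()}


@dataclass
class LSTMState:
    """One timestep's state; gate activations exposed for testing."""

    h: Tensor
    c: Tensor
    f: Tensor | None = None
    o: Tensor | None = None
    i: Tensor | None = None
    g: Tensor | None = None

    @classmethod
    def zeros(cls, batch: int, hidden: int) -> "LSTMState":
        return cls(h=Tensor(np.zeros((batch, hidden))), c=Tensor(np.zeros((batch, hidden))))


def lstm_step(x_t: Tensor, prev: LSTMState, params: LSTMParams,
              variant: str = "standard") -> LSTMState:
    """One LSTM cell update; ``variant`` selects the h_t formula."""
    if variant not in ("standard", "literal"):
        raise ValueError(f"unknown LSTM variant {variant!r}")
    if x_t.shape[-1] != params.input_dim:
        raise ValueError(
            f"input width {x_t.shape[-1]} != expected {params.input_dim}"
        )
    f = (x_t @ params.W_f + prev.h @ params.U_f + params.b_f).sigmoid()
    o = (x_t @ params.W_o + prev.h @ params.U_o + params.b_o).sigmoid()
    g = (x_t @ params.W_g + prev.h @ params.U_g + params.b_g).tanh()
    i = (x_t @ params.W_i + prev.h @ params.U_i + params.b_i).sigmoid()
    c = f * prev.c + i * g
    h = o * (c.tanh() if variant == "standard" else prev.c.tanh())
    return LSTMState(h=h, c=c, f=f, o=o, i=i, g=g)


def _run_lstm(X: Tensor, params: LSTMParams, mask: np.ndarray,
              variant: str) -> Tensor:
    """Run an LSTM over (B, T, Din); padded steps carry state through."""
    B, T, _ = X.shape
    H = params.hidden_size
    state = LSTMState.zeros(B, H)
    rows = []
    for t in range(T):
        new = lstm_step(X.select_time(t), state, params, variant)
        m = mask[:, t : t + 1].astype(np.float64)
        if m.all():
            state = new
        else:  # carry previous state through padded steps
            state = LSTMState(
                h=new.h * m + state.h * (1.0 - m),
                c=new.c * m + state.c * (1.0 - m),
            )
        rows.append(state.h)
    return stack(rows, axis=1)  # (B, T, H)


def bilstm_encode(X: Tensor, params_fwd: LSTMParams, params_bwd: LSTMParams,
                  mask: np.ndarray, variant: str = "standard") -> Tensor:
    """Bi-LSTM over a padded batch -> (B, T, 2H); padded rows are zero.

    The backward direction consumes each sequence reversed within its
    true length, so padding never enters either recurrence.
    """
    B, T, _ = X.shape
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (B, T):
        raise ValueError(f"mask shape {mask.shape} != {(B, T)}")
    lengths = mask.sum(axis=1)
    h_fwd = _run_lstm(X, params_fwd, mask, variant)

    t_idx = np.arange(T)[None, :]
    rev_idx = np.where(t_idx < lengths[:, None], lengths[:, None] - 1 - t_idx, t_idx)
    h_bwd = _run_lstm(X.take_time(rev_idx), params_bwd, mask, variant).take_time(rev_idx)

    out = concat([h_fwd, h_bwd], axis=-1)
    return out * mask[:, :, None].astype(np.float64)


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor,
                         mask: np.ndarray | None = None,
                         scale: float | None = None):
    """``softmax(Q K^T / scale) V``; returns (output, attention weights).

    ``mask`` flags valid *key* positions; masked logits get -1e30 so
    their softmax weight is exactly zero.  Default scale is the square
    root of the key width.
    """
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"query width {Q.shape[-1]} != key width {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("key and value row counts differ")
    if scale is None:
        scale = float(np.sqrt(K.shape[-1]))
    logits = (Q @ K.T) * (1.0 / scale)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        bias = np.where(mask, 0.0, NEG_INF)[..., None, :]  # broadcast over queries
        logits = logits + Tensor(np.broadcast_to(bias, logits.shape).copy())
    weights = logits.softmax(axis=-1)
    return weights @ V, weights


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections (d -> d/h) plus output projection."""

    W_Q: list[Tensor]
    W_K: list[Tensor]
    W_V: list[Tensor]
    W_O: Tensor
    n_heads: int
    d_model: int
    scale_variant: str = "per_head"  # or "literal" (sqrt(d) as printed)

    @classmethod
    def create(cls, rng: np.random.Generator, d_model: int, n_heads: int,
               scale_variant: str = "per_head") -> "AttentionParams":
        if d_model % n_heads != 0:
            raise ValueError(f"model width {d_model} not divisible by {n_heads} heads")
        dh = d_model // n_heads
        mk = lambda din, dout: Tensor(glorot(rng, din, dout), requires_grad=True)
        return cls(
            W_Q=[mk(d_model, dh) for _ in range(n_heads)],
            W_K=[mk(d_model, dh) for _ in range(n_heads)],
            W_V=[mk(d_model, dh) for _ in range(n_heads)],
            W_O=mk(d_model, d_model),
            n_heads=n_heads,
            d_model=d_model,
            scale_variant=scale_variant,
        )

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        for k in range(self.n_heads):
            out[f"{prefix}.W_Q{k}"] = self.W_Q[k]
            out[f"{prefix}.W_K{k}"] = self.W_K[k]
            out[f"{prefix}.W_V{k}"] = self.W_V[k]
        out[f"{prefix}.W_O"] = self.W_O
        return out


def multihead_attention(X: Tensor, params: AttentionParams,
                        mask: np.ndarray | None = None) -> Tensor:
    """Multihead self-attention: heads computed on projected Q=K=V=X,
    concatenated and projected back to width d."""
    if X.shape[-1] != params.d_model:
        raise ValueError(f"input width {X.shape[-1]} != model width {params.d_model}")
    scale = float(
        np.sqrt(params.d_model if params.scale_variant == "literal" else params.head_dim)
    )
    heads = []
    for k in range(params.n_heads):
        out, _ = scaled_dot_attention(
            X @ params.W_Q[k], X @ params.W_K[k], X @ params.W_V[k],
            mask=mask, scale=scale,
        )
        heads.append(out)
    return concat(heads, axis=-1) @ params.W_O


@dataclass
class PoolingParams:
    """Attention pooling: scores v^T tanh(W h_t), softmax over tokens."""

    W: Tensor
    v: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, d_model: int, attn_dim: int) -> "PoolingParams":
        return cls(
            W=Tensor(glorot(rng, d_model, attn_dim), requires_grad=True),
            # random direction so the pooling scores break symmetry and
            # can concentrate on informative tokens early in training
            v=Tensor(rng.standard_normal(attn_dim), requires_grad=True),
        )

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.v": self.v}


def attention_pool(H: Tensor, params: PoolingParams,
                   mask: np.ndarray | None = None):
    """Collapse (B, T, d) (or (T, d)) to a sentence vector.

    Returns (pooled, weights); weights sum to 1 over unmasked positions
    and are exposed for the attention-keyword report.
    """
    scores = (H @ params.W).tanh() @ params.v  # (B, T) or (T,)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=-1).all():
            raise ValueError("a sequence with every position masked cannot be pooled")
        scores = scores + Tensor(np.where(mask, 0.0, NEG_INF))
    weights = scores.softmax(axis=-1)
    pooled = (weights.reshape(*weights.shape, 1) * H).sum(axis=-2)
    return pooled, weights


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Dimensions and variants of the classifier.

    ``hidden_size`` is per direction (the reference setting is 300,
    giving a 600-wide Bi-LSTM output split over 6 heads of width 100);
    smaller values are appropriate for desk-scale synthetic corpora.
    """

    context_dim: int
    pos_vocab_size: int  # number of POS tags
    pos_emb_dim: int = 50
    position_emb_dim: int = 50
    clip_distance: int = 30
    hidden_size: int = 300
    n_heads: int = 6
    attn_pool_dim: int = 64
    n_classes: int = 6
    dropout_input: float = 0.5
    dropout_output: float = 0.5
    lstm_variant: str = "standard"
    scale_variant: str = "per_head"
    # Residual connection around the attention block.  Without it,
    # self-attention maps every position toward the same attended
    # mixture, which leaves the pooling layer nothing positional to
    # weight — the attention-keyword report then degenerates to token
    # frequency.  The skip keeps per-position identity; disable for the
    # plain attention stack.
    attention_residual: bool = True

    @property
    def input_dim(self) -> int:
        return self.context_dim + 2 * self.position_emb_dim + self.pos_emb_dim

    @property
    def d_model(self) -> int:
        return 2 * self.hidden_size


class RelationModel:
    """Bi-LSTM + multihead attention classifier over candidate pairs."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        if config.d_model % config.n_heads != 0:
            raise ValueError(
                f"Bi-LSTM output width {config.d_model} is not divisible by "
                f"{config.n_heads} attention heads"
            )
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        n_positions = 2 * config.clip_distance + 1
        self.emb_dist_chem = Tensor(
            0.1 * rng.standard_normal((n_positions, config.position_emb_dim)),
            requires_grad=True,
        )
        self.emb_dist_gene = Tensor(
            0.1 * rng.standard_normal((n_positions, config.position_emb_dim)),
            requires_grad=True,
        )
        self.emb_pos_tag = Tensor(
            0.1 * rng.standard_normal((config.pos_vocab_size, config.pos_emb_dim)),
            requires_grad=True,
        )
        self.lstm_fwd = LSTMParams.create(rng, config.input_dim, config.hidden_size)
        self.lstm_bwd = LSTMParams.create(rng, config.input_dim, config.hidden_size)
        self.attention = AttentionParams.create(
            rng, config.d_model, config.n_heads, config.scale_variant
        )
        self.pooling = PoolingParams.create(rng, config.d_model, config.attn_pool_dim)
        self.W_out = Tensor(glorot(rng, config.d_model, config.n_classes), requires_grad=True)
        self.b_out = Tensor(np.zeros(config.n_classes), requires_grad=True)
        # ELMo-style mixing over the language-model layer stack: softmax
        # normalized scalars + a global scale, trained with the task.
        self.mix_scalars: Tensor | None = None
        self.mix_gamma = Tensor(np.array(1.0), requires_grad=True)

    # -- parameters ----------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out = {
            "emb_dist_chem": self.emb_dist_chem,
            "emb_dist_gene": self.emb_dist_gene,
            "emb_pos_tag": self.emb_pos_tag,
            "W_out": self.W_out,
            "b_out": self.b_out,
            "mix_gamma": self.mix_gamma,
        }
        out.update(self.lstm_fwd.named("lstm_fwd"))
        out.update(self.lstm_bwd.named("lstm_bwd"))
        out.update(self.attention.named("attn"))
        out.update(self.pooling.named("pool"))
        if self.mix_scalars is not None:
            out["mix_scalars"] = self.mix_scalars
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        if "mix_scalars" in state and self.mix_scalars is None:
            self.mix_scalars = Tensor(state["mix_scalars"], requires_grad=True)
        for k, v in self.parameters().items():
            v.data = state[k].copy()

    # -- forward -------------------------------------------------------
    def _mix_context(self, stacks: np.ndarray) -> Tensor:
        """(B, L+1, T, d_ctx) frozen layer stacks -> (B, T, d_ctx)."""
        n_layers = stacks.shape[1]
        if self.mix_scalars is None:
            self.mix_scalars = Tensor(np.zeros(n_layers), requires_grad=True)
        if self.mix_scalars.shape[0] != n_layers:
            raise ValueError("layer-stack depth changed between batches")
        w = self.mix_scalars.softmax().reshape(1, n_layers, 1, 1)
        return (w * Tensor(stacks)).sum(axis=1) * self.mix_gamma

    def forward(self, batch: Batch, context_stacks: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None):
        """Compute class log-probabilities for a padded batch.

        ``context_stacks`` is the frozen (B, L+1, T, d_ctx) layer stack
        from the contextualizer.  Dropout (inverted, on the concatenated
        input embeddings and on the pooled vector) is active only when
        ``train`` is true, in which case ``rng`` must be supplied.

        Returns (log_probs (B, 6), pooling weights (B, T) ndarray).
        """
        cfg = self.config
        ctx = self._mix_context(context_stacks)
        if ctx.shape[-1] != cfg.context_dim:
            raise ValueError(
                f"context width {ctx.shape[-1]} != configured {cfg.context_dim}"
            )
        x = concat(
            [
                ctx,
                self.emb_dist_chem.take_rows(batch.dist_chem),
                self.emb_dist_gene.take_rows(batch.dist_gene),
                self.emb_pos_tag.take_rows(batch.pos_tag_ids),
            ],
            axis=-1,
        )
        if train and cfg.dropout_input > 0:
            keep = 1.0 - cfg.dropout_input
            x = x * (rng.random(x.shape) < keep).astype(np.float64) * (1.0 / keep)
        h = bilstm_encode(x, self.lstm_fwd, self.lstm_bwd, batch.mask, cfg.lstm_variant)
        m = multihead_attention(h, self.attention, mask=batch.mask)
        if cfg.attention_residual:
            m = h + m
        pooled, weights = attention_pool(m, self.pooling, mask=batch.mask)
        if train and cfg.dropout_output > 0:
            keep = 1.0 - cfg.dropout_output
            pooled = pooled * (rng.random(pooled.shape) < keep).astype(np.float64) * (1.0 / keep)
        log_probs = (pooled @ self.W_out + self.b_out).log_softmax(axis=-1)
        return log_probs, weights.data

    def predict(self, instances, provider, batch_size: int = 64):
        """Label a list of featurized instances in evaluation mode.

        Returns (predicted label ids, probabilities, pooling weights per
        instance trimmed to true length).
        """
        from .features import iter_batches

        preds, probs, pool_weights = [], [], []
        for batch in iter_batches(instances, batch_size):
            stacks = provider.batch_stacks(batch)
            log_p, w = self.forward(batch, stacks, train=False)
            p = np.exp(log_p.data)
            preds.extend(np.argmax(p, axis=1).tolist())
            probs.extend(p)
            for i, length in enumerate(batch.lengths):
                pool_weights.append(w[i, :length])
        return np.array(preds), np.array(probs), pool_weights

    # -- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        state = self.get_state()
        np.savez(path, __config__=json.dumps(asdict(self.config)), **state)

    @classmethod
    def load(cls, path) -> "RelationModel":
        payload = np.load(path, allow_pickle=False)
        config = ModelConfig(**json.loads(str(payload["__config__"])))
        model = cls(config)
        state = {k: payload[k] for k in payload.files if k != "__config__"}
        model.set_state(state)
        return model
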