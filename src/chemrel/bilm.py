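"""Contextual token representations from a bidirectional language model.

A forward LM factorizes the sentence probability as

    P(w_1..w_n) = prod_k p(w_k | w_1..w_{k-1})

and a backward LM as ``prod_k p(w_k | w_{k+1}..w_n)``; the joint
training objective is the sum of the two log-likelihoods over tokens.
Per-token contextual representations are formed ELMo-style: the
embedding layer and every LSTM layer (forward and backward states
concatenated) form a stack of L+1 matrices, combined with
softmax-normalized scalar weights and a global scale.  The same word
therefore receives different vectors in different sentences.

The LM here is deliberately small and trainable on the task corpus (or
synthetic text): it exposes the same provider interface as precomputed
contextual embeddings, so externally computed vectors can be swapped in.
The LM is trained separately and frozen during task training; only the
mixing weights are trained with the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, stack
from .model import LSTMParams, LSTMState, lstm_step
from .optim import RMSProp


@dataclass
class BiLMConfig:
    vocab_size: int
    hidden_dim: int = 16
    layers: int = 1
    embedding_dim: int | None = None  # defaults to hidden_dim
    tie_embeddings: bool = False

    def __post_init__(self):
        if self.embedding_dim is None:
            self.embedding_dim = self.hidden_dim
        if self.embedding_dim != self.hidden_dim:
            raise ValueError(
                "embedding_dim must equal hidden_dim so all layers of the "
                "representation stack share one width"
            )
        if min(self.vocab_size, self.hidden_dim, self.layers) < 1:
            raise ValueError("all dimensions must be positive")


@dataclass
class ContextRepresentation:
    """Layer stack and mixing weights for one sentence."""

    layer_stack: np.ndarray  # (L+1, n, 2H)
    weights: np.ndarray  # raw scalars, softmax-normalized before use
    gamma: float = 1.0

    @property
    def normalized_weights(self) -> np.ndarray:
        e = np.exp(self.weights - self.weights.max())
        return e / e.sum()

    @property
    def matrix(self) -> np.ndarray:
        w = self.normalized_weights
        return self.gamma * np.tensordot(w, self.layer_stack, axes=(0, 0))


class BiLM:
    """Small trainable bidirectional LSTM language model."""

    def __init__(self, config: BiLMConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        V, E, H = config.vocab_size, config.embedding_dim, config.hidden_dim
        # two extra embedding rows: BOS (=V) and EOS (=V+1)
        # unit-scale embeddings keep token identity strongly present in
        # the representation stack's first layer
        self.embedding = Tensor(rng.standard_normal((V + 2, E)), requires_grad=True)
        self.lstms = {
            "forward": [
                LSTMParams.create(rng, E if l == 0 else H, H)
                for l in range(config.layers)
            ],
            "backward": [
                LSTMParams.create(rng, E if l == 0 else H, H)
                for l in range(config.layers)
            ],
        }
        if config.tie_embeddings:
            self.W_out = None  # use embedding rows as the output projection
        else:
            self.W_out = Tensor(
                np.sqrt(6.0 / (H + V)) * (2 * rng.random((H, V)) - 1), requires_grad=True
            )
        self.b_out = Tensor(np.zeros(V), requires_grad=True)

    @property
    def bos(self) -> int:
        return self.config.vocab_size

    @property
    def eos(self) -> int:
        return self.config.vocab_size + 1

    @property
    def stack_depth(self) -> int:
        return self.config.layers + 1

    @property
    def width(self) -> int:
        return 2 * self.config.hidden_dim

    def parameters(self) -> dict[str, Tensor]:
        out = {"embedding": self.embedding, "b_out": self.b_out}
        if self.W_out is not None:
            out["W_out"] = self.W_out
        for direction, layers in self.lstms.items():
            for l, p in enumerate(layers):
                out.update(p.named(f"{direction}.{l}"))
        return out

    # -- internals -----------------------------------------------------
    def _output_logits(self, h: Tensor) -> Tensor:
        if self.W_out is None:
            proj = self.embedding.take_rows(np.arange(self.config.vocab_size)).T
            return h @ proj + self.b_out
        return h @ self.W_out + self.b_out

    def _run_layers(self, ids: np.ndarray, direction: str,
                    mask: np.ndarray | None = None) -> list[Tensor]:
        """Run the LSTM stack over (B, T) ids; returns per-layer (B, T, H)."""
        B, T = ids.shape
        x = self.embedding.take_rows(ids)
        outs = []
        for params in self.lstms[direction]:
            state = LSTMState.zeros(B, params.hidden_size)
            rows = []
            for t in range(T):
                new = lstm_step(x.select_time(t), state, params)
                if mask is None or mask[:, t].all():
                    state = new
                else:
                    m = mask[:, t : t + 1].astype(np.float64)
                    state = LSTMState(h=new.h * m + state.h * (1 - m),
                                      c=new.c * m + state.c * (1 - m))
                rows.append(state.h)
            x = stack(rows, axis=1)
            outs.append(x)
        return outs

    @staticmethod
    def _reverse_within(ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        T = ids.shape[1]
        t_idx = np.arange(T)[None, :]
        rev = np.where(t_idx < lengths[:, None], lengths[:, None] - 1 - t_idx, t_idx)
        return np.take_along_axis(ids, rev, axis=1)

    def _direction_log_probs(self, ids: np.ndarray, lengths: np.ndarray,
                             direction: str, mask: np.ndarray) -> Tensor:
        """(B, T) per-position log p(target) in the direction's own order."""
        if ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id outside the language-model vocabulary")
        if direction == "forward":
            targets = ids
            inputs = np.concatenate(
                [np.full((ids.shape[0], 1), self.bos, dtype=ids.dtype), ids[:, :-1]],
                axis=1,
            )
        else:
            targets = self._reverse_within(ids, lengths)
            inputs = np.concatenate(
                [np.full((ids.shape[0], 1), self.eos, dtype=ids.dtype), targets[:, :-1]],
                axis=1,
            )
        h = self._run_layers(inputs, direction, mask)[-1]
        log_probs = self._output_logits(h).log_softmax(axis=-1)
        onehot = np.zeros(log_probs.shape)
        b_idx, t_idx = np.nonzero(mask)
        onehot[b_idx, t_idx, targets[b_idx, t_idx]] = 1.0
        return (log_probs * onehot).sum(axis=-1)  # zeros at padded slots

    # -- public API ----------------------------------------------------
    def log_likelihood(self, token_ids, direction: str) -> np.ndarray:
        """Per-token log p(w_k | context) for one sequence, in w_1..w_n order.

        ``forward`` conditions on w_1..w_{k-1} only, ``backward`` on
        w_{k+1}..w_n only; the causality tests perturb the other side to
        confirm it.
        """
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {direction!r}")
        ids = np.asarray(token_ids, dtype=np.int64)[None, :]
        if ids.shape[1] == 0:
            raise ValueError("empty sequence")
        lengths = np.array([ids.shape[1]])
        mask = np.ones(ids.shape, dtype=bool)
        lp = self._direction_log_probs(ids, lengths, direction, mask).data[0]
        return lp if direction == "forward" else lp[::-1].copy()

    def joint_log_likelihood(self, token_ids) -> float:
        """Joint bidirectional objective: forward sum + backward sum."""
        return float(
            self.log_likelihood(token_ids, "forward").sum()
            + self.log_likelihood(token_ids, "backward").sum()
        )

    def layer_stack(self, token_ids) -> np.ndarray:
        """Representation stack (L+1, n, 2H) for one sentence.

        Layer 0 duplicates the static embedding (forward half ==
        backward half); layer l >= 1 concatenates the forward and
        backward LSTM hidden states of that layer.
        """
        ids = np.asarray(token_ids, dtype=np.int64)[None, :]
        if ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id outside the language-model vocabulary")
        emb = self.embedding.data[ids[0]]
        fwd = self._run_layers(ids, "forward")
        rev = ids[:, ::-1].copy()
        bwd = self._run_layers(rev, "backward")
        layers = [np.concatenate([emb, emb], axis=-1)]
        for f, b in zip(fwd, bwd):
            layers.append(
                np.concatenate([f.data[0], b.data[0][::-1]], axis=-1)
            )
        return np.stack(layers, axis=0)

    def save(self, path) -> None:
        from dataclasses import asdict

        state = {k: v.data for k, v in self.parameters().items()}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **state)

    @classmethod
    def load(cls, path) -> "BiLM":
        payload = np.load(path, allow_pickle=False)
        config = BiLMConfig(**json.loads(str(payload["__config__"])))
        model = cls(config)
        for k, v in model.parameters().items():
            v.data = payload[k].copy()
        return model

    def perplexity(self, sequences) -> float:
        """Per-token perplexity under the averaged two-direction model."""
        total, count = 0.0, 0
        for seq in sequences:
            lp_f = self.log_likelihood(seq, "forward")
            lp_b = self.log_likelihood(seq, "backward")
            total += 0.5 * (lp_f.sum() + lp_b.sum())
            count += len(seq)
        return float(np.exp(-total / count))


def embed_sentence(token_ids, bilm: BiLM,
                   combination_weights: np.ndarray | None = None,
                   gamma: float = 1.0) -> ContextRepresentation:
    """ELMo-style mixed representation of one sentence."""
    stack_ = bilm.layer_stack(token_ids)
    if combination_weights is None:
        combination_weights = np.zeros(stack_.shape[0])
    combination_weights = np.asarray(combination_weights, dtype=np.float64)
    if combination_weights.shape != (stack_.shape[0],):
        raise ValueError("one combination weight per stack layer required")
    return ContextRepresentation(stack_, combination_weights, gamma)


def train_bilm(sequences, config: BiLMConfig, seed: int = 0,
               epochs: int = 3, lr: float = 5e-3, batch_size: int = 32,
               rmsprop_decay: float = 0.9) -> tuple[BiLM, list[float]]:
    """Train a bi-LM on integer token sequences with RMSProp.

    Returns (model, per-epoch mean negative joint log-likelihood per
    token).  Deterministic given ``seed``: parameter init, bucketing and
    shuffling all draw from one seeded generator.
    """
    sequences = [np.asarray(s, dtype=np.int64) for s in sequences if len(s) > 0]
    if not sequences:
        raise ValueError("cannot train a language model on an empty corpus")
    rng = np.random.default_rng(seed)
    model = BiLM(config, rng)
    opt = RMSProp(model.parameters(), lr=lr, decay=rmsprop_decay)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(sequences))
        total_nll, total_tokens = 0.0, 0
        for start in range(0, len(order), batch_size):
            chunk = [sequences[i] for i in order[start : start + batch_size]]
            lengths = np.array([len(s) for s in chunk])
            T = int(lengths.max())
            ids = np.zeros((len(chunk), T), dtype=np.int64)
            for i, s in enumerate(chunk):
                ids[i, : len(s)] = s
            mask = np.arange(T)[None, :] < lengths[:, None]
            lp_f = model._direction_log_probs(ids, lengths, "forward", mask)
            lp_b = model._direction_log_probs(ids, lengths, "backward", mask)
            n_tok = int(mask.sum())
            loss = (lp_f + lp_b).sum() * (-1.0 / n_tok)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_nll += float(loss.data) * n_tok
            total_tokens += n_tok
        history.append(total_nll / total_tokens)
    return model, history


# ---------------------------------------------------------------------------
# Providers: serve frozen layer stacks to the classifier
# ---------------------------------------------------------------------------

def _key(token_ids) -> str:
    return ",".join(str(int(i)) for i in token_ids)


class BiLMProvider:
    """Computes (and caches) frozen layer stacks from an in-process bi-LM."""

    def __init__(self, bilm: BiLM):
        self.bilm = bilm
        self._cache: dict[str, np.ndarray] = {}

    @property
    def width(self) -> int:
        return self.bilm.width

    @property
    def depth(self) -> int:
        return self.bilm.stack_depth

    def stack(self, token_ids) -> np.ndarray:
        key = _key(token_ids)
        if key not in self._cache:
            self._cache[key] = self.bilm.layer_stack(token_ids)
        return self._cache[key]

    def batch_stacks(self, batch) -> np.ndarray:
        """(B, L+1, T, 2H) zero-padded stacks for a featurized batch."""
        B, T = batch.token_ids.shape
        depth = self.bilm.stack_depth
        out = np.zeros((B, depth, T, self.width))
        for i, inst in enumerate(batch.instances):
            s = self.stack(inst.token_ids)
            out[i, :, : s.shape[1], :] = s
        return out

    def save(self, path, instances) -> None:
        """Persist the stacks of the given instances for later reuse."""
        payload = {f"s_{_key(inst.token_ids)}": self.stack(inst.token_ids)
                   for inst in instances}
        meta = json.dumps({"width": self.width, "depth": self.bilm.stack_depth})
        np.savez(path, __meta__=meta, **payload)


class PrecomputedProvider:
    """Serves previously saved layer stacks keyed by token-id sequence."""

    def __init__(self, stacks: dict[str, np.ndarray], width: int, depth: int):
        for key, s in stacks.items():
            if s.shape[0] != depth or s.shape[2] != width:
                raise ValueError(
                    f"stack {key!r} has shape {s.shape}, expected depth {depth} "
                    f"and width {width}"
                )
        self._stacks = stacks
        self.width = width
        self.depth = depth

    @classmethod
    def load(cls, path) -> "PrecomputedProvider":
        payload = np.load(path, allow_pickle=False)
        meta = json.loads(str(payload["__meta__"]))
        stacks = {
            k[2:]: payload[k] for k in payload.files if k.startswith("s_")
        }
        return cls(stacks, meta["width"], meta["depth"])

    def stack(self, token_ids) -> np.ndarray:
        key = _key(token_ids)
        if key not in self._stacks:
            raise KeyError(f"no precomputed representation for sentence {key!r}")
        return self._stacks[key]

    def batch_stacks(self, batch) -> np.ndarray:
        B, T = batch.token_ids.shape
        out = np.zeros((B, self.depth, T, self.width))
        for i, inst in enumerate(batch.instances):
            s = self.stack(inst.token_ids)
            out[i, :, : s.shape[1], :] = s
        return out
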