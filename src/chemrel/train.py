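"""Training protocol for the relation classifier.

Categorical cross-entropy, RMSProp (learning rate 0.001, decay 0.9,
epsilon 1e-7), mini-batches of 64, dropout 0.5 on the input embeddings
and the pooled sentence vector, a 10% instance-level validation split,
and early stopping on validation micro-F.  Experiments are repeated
over several seeds (five by default) and the arithmetic mean of the
micro metrics reported, with per-seed values retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import ConfusionMatrix, EvalReport, micro_metrics
from .features import iter_batches
from .model import ModelConfig, RelationModel
from .optim import RMSProp


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-7
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    validation_fraction: float = 0.10
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    class_weights: np.ndarray | None = None  # optional hook; off by default

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_micro_f: float


@dataclass
class RunResult:
    seed: int
    history: list[EpochRecord]
    best_epoch: int
    best_state: dict[str, np.ndarray]
    best_val_micro_f: float


def split_validation(instances, fraction: float = 0.10, seed: int = 0):
    """Uniform instance-level split into (train, validation)."""
    if len(instances) < 10:
        raise ValueError("need at least 10 instances to split")
    n_val = int(round(len(instances) * fraction))
    if n_val == 0 or n_val == len(instances):
        raise ValueError(f"fraction {fraction} yields an empty split")
    order = np.random.default_rng(seed).permutation(len(instances))
    val_idx = set(order[:n_val].tolist())
    train = [inst for i, inst in enumerate(instances) if i not in val_idx]
    val = [inst for i, inst in enumerate(instances) if i in val_idx]
    return train, val


def _nll(log_probs, labels: np.ndarray, class_weights=None):
    onehot = np.zeros(log_probs.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    if class_weights is not None:
        onehot *= np.asarray(class_weights)[labels][:, None]
    return (log_probs * onehot).sum() * (-1.0 / len(labels))


def evaluate_model(model: RelationModel, instances, provider,
                   batch_size: int = 64):
    """(mean NLL, micro-F, confusion matrix) on a fixed instance list."""
    losses, golds, preds = [], [], []
    for batch in iter_batches(instances, batch_size):
        stacks = provider.batch_stacks(batch)
        log_p, _ = model.forward(batch, stacks, train=False)
        losses.append(float(_nll(log_p, batch.labels).data) * len(batch))
        golds.extend(batch.labels.tolist())
        preds.extend(np.argmax(log_p.data, axis=1).tolist())
    cm = ConfusionMatrix.from_predictions(golds, preds)
    return sum(losses) / len(instances), micro_metrics(cm)[2], cm


def train_model(train_set, val_set, model_config: ModelConfig,
                train_config: TrainConfig, provider, seed: int = 0,
                model: RelationModel | None = None,
                log=None) -> tuple[RelationModel, RunResult]:
    """Fit the classifier; early-stop on validation micro-F.

    The best checkpoint is the epoch with maximal validation micro-F
    (earliest epoch on ties) and is restored into the returned model.
    Fully deterministic given ``seed``.
    """
    if not train_set or not val_set:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(seed)
    if model is None:
        model = RelationModel(model_config, rng)
    if model.mix_scalars is None and hasattr(provider, "depth"):
        from .autodiff import Tensor

        model.mix_scalars = Tensor(np.zeros(provider.depth), requires_grad=True)
    opt = RMSProp(model.parameters(), lr=train_config.learning_rate,
                  decay=train_config.rmsprop_decay, eps=train_config.rmsprop_eps)

    history: list[EpochRecord] = []
    best_f, best_epoch, best_state, stale = -1.0, -1, None, 0
    for epoch in range(train_config.max_epochs):
        total_loss, n_seen = 0.0, 0
        for batch in iter_batches(train_set, train_config.batch_size, rng):
            stacks = provider.batch_stacks(batch)
            log_p, _ = model.forward(batch, stacks, train=True, rng=rng)
            loss = _nll(log_p, batch.labels, train_config.class_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; aborting training"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(batch)
            n_seen += len(batch)
        # RMSProp may lazily create mix_scalars on the first batch
        if set(opt.params) != set(model.parameters()):
            opt.params = model.parameters()
            for name, p in opt.params.items():
                opt._cache.setdefault(name, np.zeros_like(p.data))
        val_loss, val_f, _ = evaluate_model(model, val_set, provider,
                                            train_config.batch_size)
        record = EpochRecord(epoch, total_loss / n_seen, val_loss, val_f)
        history.append(record)
        if log is not None:
            log(f"epoch={epoch} train_loss={record.train_loss:.4f} "
                f"val_loss={val_loss:.4f} val_micro_f={val_f:.4f}")
        if val_f > best_f:
            best_f, best_epoch, best_state, stale = val_f, epoch, model.get_state(), 0
        else:
            stale += 1
            if stale >= train_config.patience:
                break
    model.set_state(best_state)
    return model, RunResult(seed, history, best_epoch, best_state, best_f)


@dataclass
class RepeatedRuns:
    per_seed: list[tuple[int, EvalReport]]
    mean_micro: tuple[float, float, float]

    @property
    def micro_f_values(self) -> list[float]:
        return [rep.micro[2] for _, rep in self.per_seed]


def repeat_runs(instances, model_config: ModelConfig, train_config: TrainConfig,
                provider, test_instances=None, log=None) -> RepeatedRuns:
    """Run the full protocol once per seed and average the micro metrics.

    Each seed resamples the validation split, re-initializes the model
    and re-trains; evaluation is on ``test_instances`` when given, else
    on that seed's validation split.
    """
    if not train_config.seeds:
        raise ValueError("at least one seed required")
    per_seed = []
    for seed in train_config.seeds:
        tr, val = split_validation(instances, train_config.validation_fraction, seed)
        model, _ = train_model(tr, val, model_config, train_config, provider,
                               seed=seed, log=log)
        eval_set = test_instances if test_instances is not None else val
        _, _, cm = evaluate_model(model, eval_set, provider, train_config.batch_size)
        per_seed.append((seed, EvalReport.from_confusion(cm)))
    micro = np.array([rep.micro for _, rep in per_seed])
    return RepeatedRuns(per_seed, tuple(micro.mean(axis=0)))
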