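"""End-to-end orchestration: corpus -> candidates -> features -> model.

``run_experiment`` is the canonical workflow: build candidate instances
from a (possibly synthetic) corpus, pretrain the small bidirectional
language model on the corpus sentences, freeze it, train the classifier
with the standard protocol and score it.  Model sizes default to
desk-scale settings appropriate for synthetic corpora; the reference
full-scale settings (300 hidden units per direction, 6 heads of width
100) remain available through :class:`chemrel.model.ModelConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bilm import BiLM, BiLMConfig, BiLMProvider, train_bilm
from .corpus import (
    CandidateReport,
    Document,
    EntityMention,
    RelationAnnotation,
    generate_candidates,
    read_corpus,
)
from .evaluate import ConfusionMatrix, EvalReport, attention_keywords, micro_metrics
from .features import FeaturizedInstance, Vocabulary, featurize
from .model import ModelConfig, RelationModel
from .train import RunResult, TrainConfig, evaluate_model, split_validation, train_model


@dataclass
class Dataset:
    instances: list[FeaturizedInstance]
    token_vocab: Vocabulary
    pos_vocab: Vocabulary
    candidates: list
    report: CandidateReport


def build_dataset(
    documents: list[Document],
    mentions: list[EntityMention],
    relations: list[RelationAnnotation],
    clip_distance: int = 30,
    anonymize: str = "targets",
    token_vocab: Vocabulary | None = None,
    pos_vocab: Vocabulary | None = None,
) -> Dataset:
    """Candidate generation + featurization over a parsed corpus.

    Fresh vocabularies are built and frozen unless existing (frozen)
    ones are passed in, in which case unseen tokens map to OOV.
    """
    report = CandidateReport()
    by_doc_mentions: dict[str, list[EntityMention]] = {}
    for m in mentions:
        by_doc_mentions.setdefault(m.doc_id, []).append(m)
    candidates = []
    doc_of = {}
    for doc in documents:
        cands = generate_candidates(
            doc, by_doc_mentions.get(doc.doc_id, []), relations, report=report
        )
        candidates.extend(cands)
        doc_of[doc.doc_id] = doc
    freeze = token_vocab is None
    token_vocab = token_vocab if token_vocab is not None else Vocabulary()
    pos_vocab = pos_vocab if pos_vocab is not None else Vocabulary()
    instances = [
        featurize(
            c,
            doc_of[c.doc_id],
            token_vocab,
            pos_vocab,
            clip_distance,
            by_doc_mentions.get(c.doc_id, []),
            anonymize,
        )
        for c in candidates
    ]
    if freeze:
        token_vocab.freeze()
        pos_vocab.freeze()
    return Dataset(instances, token_vocab, pos_vocab, candidates, report)


def load_dataset(corpus_dir, **kwargs) -> tuple[Dataset, tuple]:
    """Read a three-file corpus directory and build its dataset."""
    corpus_dir = Path(corpus_dir)
    docs, mentions, relations = read_corpus(
        corpus_dir / "abstracts.tsv",
        corpus_dir / "entities.tsv",
        corpus_dir / "relations.tsv",
    )
    return build_dataset(docs, mentions, relations, **kwargs), (docs, mentions, relations)


@dataclass
class ExperimentConfig:
    """Desk-scale defaults for synthetic-corpus experiments."""

    clip_distance: int = 10
    anonymize: str = "targets"
    bilm_hidden: int = 12
    bilm_layers: int = 1
    bilm_epochs: int = 2
    bilm_lr: float = 5e-3
    hidden_size: int = 24  # per direction
    n_heads: int = 4
    position_emb_dim: int = 8
    pos_emb_dim: int = 8
    attn_pool_dim: int = 16
    dropout_input: float = 0.5
    dropout_output: float = 0.5

    def model_config(self, context_dim: int, pos_vocab_size: int) -> ModelConfig:
        return ModelConfig(
            context_dim=context_dim,
            pos_vocab_size=pos_vocab_size,
            pos_emb_dim=self.pos_emb_dim,
            position_emb_dim=self.position_emb_dim,
            clip_distance=self.clip_distance,
            hidden_size=self.hidden_size,
            n_heads=self.n_heads,
            attn_pool_dim=self.attn_pool_dim,
            dropout_input=self.dropout_input,
            dropout_output=self.dropout_output,
        )


@dataclass
class ExperimentResult:
    model: RelationModel
    provider: BiLMProvider
    dataset: Dataset
    run: RunResult
    report: EvalReport
    keywords: dict[str, list[str]]
    val_instances: list[FeaturizedInstance] = field(default_factory=list)


def pretrain_bilm(dataset: Dataset, config: ExperimentConfig, seed: int) -> BiLMProvider:
    """Train the bi-LM on the corpus's unique sentences and freeze it."""
    seen, sequences = set(), []
    for inst in dataset.instances:
        key = inst.sentence_key
        if key not in seen:
            seen.add(key)
            sequences.append(inst.token_ids)
    bilm, _ = train_bilm(
        sequences,
        BiLMConfig(
            vocab_size=len(dataset.token_vocab),
            hidden_dim=config.bilm_hidden,
            layers=config.bilm_layers,
        ),
        seed=seed,
        epochs=config.bilm_epochs,
        lr=config.bilm_lr,
    )
    return BiLMProvider(bilm)


def run_experiment(
    documents,
    mentions,
    relations,
    config: ExperimentConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    eval_instances: list[FeaturizedInstance] | None = None,
    log=None,
) -> ExperimentResult:
    """The full workflow on one corpus with one seed.

    Evaluation (report, confusion, keywords) is on the held-out
    validation split unless ``eval_instances`` is given.
    """
    config = config if config is not None else ExperimentConfig()
    train_config = train_config if train_config is not None else TrainConfig()
    dataset = build_dataset(
        documents, mentions, relations, config.clip_distance, config.anonymize
    )
    provider = pretrain_bilm(dataset, config, seed)
    model_config = config.model_config(provider.width, len(dataset.pos_vocab))
    train_set, val_set = split_validation(
        dataset.instances, train_config.validation_fraction, seed
    )
    model, run = train_model(
        train_set, val_set, model_config, train_config, provider, seed=seed, log=log
    )
    target = eval_instances if eval_instances is not None else val_set
    preds, _, pool_weights = model.predict(target, provider, train_config.batch_size)
    cm = ConfusionMatrix.from_predictions([f.label_id for f in target], preds)
    keywords = attention_keywords(target, pool_weights, preds, k=5)
    report = EvalReport.from_confusion(cm, keywords)
    return ExperimentResult(model, provider, dataset, run, report, keywords, val_set)
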