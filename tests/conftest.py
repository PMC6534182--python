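"""Shared fixtures: synthetic corpora and tiny model configurations."""

from __future__ import annotations

import numpy as np
import pytest

from chemrel.pipeline import ExperimentConfig, build_dataset
from chemrel.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """~160-instance easy corpus (trigger strength 1, no distractors)."""
    return generate_corpus(SynthConfig(n_docs=30, sentences_per_doc=(3, 6), seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    return build_dataset(
        small_corpus.documents,
        small_corpus.mentions,
        small_corpus.relations,
        clip_distance=10,
    )


@pytest.fixture()
def tiny_model_config():
    """Dimensions small enough for finite-difference gradient checks."""
    return ExperimentConfig(
        clip_distance=5,
        bilm_hidden=4,
        hidden_size=6,
        n_heads=2,
        position_emb_dim=3,
        pos_emb_dim=3,
        attn_pool_dim=4,
        dropout_input=0.0,
        dropout_output=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
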