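"""Synthetic ChemProt-format corpora with controllable difficulty.

The generator emits the exact three-file TSV dialect of
:mod:`chemrel.corpus` plus ground-truth instance labels, so every
pipeline stage — parsing, candidate pairing, featurization, training,
scoring — is exercisable without downloads.

Statistical structure: each sentence hosts one (chemical, gene) pair
drawn with a configurable class mixture; with probability
``trigger_strength`` the class's trigger keyword (lexicons seeded from
the attention keywords typical of each CPR class: e.g. "inhibitor" for
CPR:4, "agonist" for CPR:5, "antagonist" for CPR:6) is planted near the
pair, otherwise a neutral verb is used.  At trigger strength 1 with no
distractors the label is a deterministic function of the trigger, so a
keyword-matching baseline — and hence the Bayes-optimal classifier —
scores micro-F 1.0.  Difficulty dials: passive-voice templates,
multi-clause sentences, distractor clauses carrying extra unrelated
entities, and cross-class trigger confounds between CPR:3 and CPR:4
(the empirically confusable pair).

Templates are slot-filling frames over a Zipf-distributed filler
vocabulary rather than a grammar: difficulty is controllable and the
Bayes-optimal behavior transparent.  Entity surfaces are synthetic
alphanumeric identifiers (CHM####, GEN####); no chemical lexicon is
needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import (
    LABELS,
    Document,
    EntityMention,
    RelationAnnotation,
    split_sentences,
    write_corpus,
)

DEFAULT_TRIGGERS: dict[str, tuple[str, ...]] = {
    "CPR:3": ("expression", "increased", "induced", "activation", "activity"),
    "CPR:4": ("inhibitor", "inhibition", "inhibitors", "inhibited"),
    "CPR:5": ("agonist", "agonists", "selective"),
    "CPR:6": ("antagonist", "antagonists"),
    "CPR:9": ("metabolism", "catalyzes", "metabolized", "uptake", "enzyme"),
}

_NEUTRAL_VERBS = ("accompanies", "colocalizes", "precedes", "follows")

# Shared ambiguous regulation vocabulary: used by *both* CPR:3 and
# CPR:4 sentences at the configured confound rate, making the two
# classes genuinely confusable (the empirically hard pair).
AMBIGUOUS_REGULATION_TRIGGERS = ("regulates", "regulated", "modulates",
                                 "regulation")
_RELATION_NAMES = {
    "CPR:2": "REGULATOR",
    "CPR:3": "UPREGULATOR",
    "CPR:4": "DOWNREGULATOR",
    "CPR:5": "AGONIST",
    "CPR:6": "ANTAGONIST",
    "CPR:9": "SUBSTRATE",
}


def default_mixture() -> dict[str, float]:
    return {"NEG": 0.5, "CPR:3": 0.1, "CPR:4": 0.1, "CPR:5": 0.1,
            "CPR:6": 0.1, "CPR:9": 0.1}


@dataclass
class SynthConfig:
    n_docs: int = 40
    sentences_per_doc: tuple[int, int] = (3, 6)
    class_mixture: dict[str, float] = field(default_factory=default_mixture)
    trigger_lexicon: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGERS)
    )
    trigger_strength: float = 1.0
    distractor_rate: float = 0.0
    passive_rate: float = 0.0
    multi_clause_rate: float = 0.0
    confound_rate: float = 0.0
    noneval_rate: float = 0.0  # rate of planted non-evaluated (CPR:2) gold
    vocab_size: int = 80
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_mixture.values()):
            raise ValueError("class mixture must be a probability distribution")
        if not set(self.class_mixture) <= set(LABELS):
            raise ValueError(f"mixture labels must come from {list(LABELS)}")
        if sum(v > 0 for v in self.class_mixture.values()) == 0:
            raise ValueError("degenerate mixture: no class has positive mass")
        if not 0.0 <= self.trigger_strength <= 1.0:
            raise ValueError("trigger strength must lie in [0, 1]")


@dataclass
class TruthRecord:
    doc_id: str
    sentence_index: int  # index into Document.sentence_spans (0 = title)
    chem_id: str
    gene_id: str
    label: str


@dataclass
class SynthCorpus:
    documents: list[Document]
    mentions: list[EntityMention]
    relations: list[RelationAnnotation]
    truth: list[TruthRecord]
    config: SynthConfig


class _SentenceBuilder:
    """Accumulates one sentence's text and entity placements."""

    def __init__(self):
        self.parts: list[str] = []
        self.entities: list[tuple[str, str, int]] = []  # surface, type, start
        self._len = 0

    def word(self, w: str) -> None:
        if self.parts:
            self._len += 1  # joining space
        self.parts.append(w)
        self._len += len(w)

    def entity(self, surface: str, category: str) -> None:
        start = self._len + (1 if self.parts else 0)
        self.word(surface)
        self.entities.append((surface, category, start))

    def text(self) -> str:
        return " ".join(self.parts)


def _build_sentence(label: str, cfg: SynthConfig, rng: np.random.Generator,
                    noise_rng: np.random.Generator, fillers: list[str],
                    zipf: np.ndarray):
    """Returns (_SentenceBuilder, chem surface, gene surface, gene type).

    ``noise_rng`` drives the distractor clause only, so at a fixed seed
    the planted relations are invariant to the distractor rate.
    """
    b = _SentenceBuilder()

    def filler(gen=None) -> str:
        gen = gen if gen is not None else rng
        return fillers[gen.choice(len(fillers), p=zipf)]

    chem = f"CHM{rng.integers(0, 10000):04d}"
    gene = f"GEN{rng.integers(0, 10000):04d}"
    gene_type = "GENE-Y" if rng.random() < 0.7 else "GENE-N"

    if label != "NEG" and rng.random() < cfg.trigger_strength:
        if label in ("CPR:3", "CPR:4") and rng.random() < cfg.confound_rate:
            trig = str(rng.choice(AMBIGUOUS_REGULATION_TRIGGERS))
        else:
            trig = str(rng.choice(cfg.trigger_lexicon[label]))
    else:
        trig = str(rng.choice(_NEUTRAL_VERBS))

    u = rng.random()
    if u < cfg.passive_rate:
        frame = "passive"
    elif u < cfg.passive_rate + cfg.multi_clause_rate:
        frame = "multi"
    else:
        frame = "active"

    if frame == "passive":
        b.word("the")
        b.entity(gene, gene_type)
        b.word("was")
        b.word(trig)
        b.word("by")
        b.entity(chem, "CHEMICAL")
        b.word("in")
        b.word(filler())
        b.word(filler())
    elif frame == "multi":
        b.word("although")
        for _ in range(int(rng.integers(3, 6))):
            b.word(filler())
        b.word(",")
        b.entity(chem, "CHEMICAL")
        b.word(trig)
        b.word("the")
        b.entity(gene, gene_type)
        b.word(",")
        b.word("whereas")
        for _ in range(int(rng.integers(2, 5))):
            b.word(filler())
    else:
        b.entity(chem, "CHEMICAL")
        b.word(trig)
        b.word("the")
        b.entity(gene, gene_type)
        b.word("in")
        for _ in range(int(rng.integers(1, 4))):
            b.word(filler())

    if noise_rng.random() < cfg.distractor_rate:
        b.word(",")
        b.word("and")
        if noise_rng.random() < 0.5:
            b.entity(f"CHM{noise_rng.integers(0, 10000):04d}", "CHEMICAL")
        else:
            b.entity(f"GEN{noise_rng.integers(0, 10000):04d}",
                     "GENE-Y" if noise_rng.random() < 0.7 else "GENE-N")
        b.word(filler(noise_rng))
        b.word(filler(noise_rng))
    b.word(".")
    return b, chem, gene, gene_type


def generate_corpus(config: SynthConfig, out_dir=None) -> SynthCorpus:
    """Generate a corpus; deterministic byte-identical files given a seed."""
    rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(2**31 + config.seed)
    fillers = [f"tk{i:03d}" for i in range(config.vocab_size)]
    ranks = np.arange(1, config.vocab_size + 1, dtype=np.float64)
    zipf = (1.0 / ranks) / (1.0 / ranks).sum()

    labels = sorted(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in labels])

    documents, mentions, relations, truth = [], [], [], []
    for d in range(config.n_docs):
        doc_id = f"9{d:06d}"
        title = f"synthetic abstract {d} concerning {fillers[rng.choice(len(fillers), p=zipf)]}"
        lo, hi = config.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        abstract_parts: list[str] = []
        doc_entities: list[tuple[str, str, int]] = []  # surface, type, abs offset
        sent_records = []
        abstract_len = 0
        for s in range(n_sent):
            label = labels[int(rng.choice(len(labels), p=probs))]
            b, chem, gene, gene_type = _build_sentence(
                label, config, rng, noise_rng, fillers, zipf
            )
            sent_offset = abstract_len + (1 if abstract_parts else 0)
            for surface, category, start in b.entities:
                doc_entities.append((surface, category, sent_offset + start))
            text = b.text()
            abstract_parts.append(text)
            abstract_len = sent_offset + len(text)
            sent_records.append((s, label, chem, gene))
        abstract = " ".join(abstract_parts)
        doc = Document(doc_id, title, abstract)
        doc.sentence_spans = split_sentences(doc.full_text)
        documents.append(doc)

        base = len(title) + 1  # title + tab separator
        ent_ids: dict[int, str] = {}
        doc_mentions = []
        for i, (surface, category, offset) in enumerate(doc_entities):
            ent_id = f"T{i + 1}"
            start = base + offset
            m = EntityMention(doc_id, ent_id, category, start, start + len(surface), surface)
            doc_mentions.append(m)
            ent_ids[start] = ent_id
        mentions.extend(doc_mentions)

        # map (sentence order) -> entity ids of the target pair: the target
        # chem/gene are the first chemical and first gene placed per sentence
        by_pos = sorted(doc_mentions, key=lambda m: m.char_start)
        sent_of = {}
        for m in by_pos:
            for si, (s0, e0) in enumerate(doc.sentence_spans):
                if m.char_start >= s0 and m.char_end <= e0:
                    sent_of[m.entity_id] = si
                    break
        for s, label, chem, gene in sent_records:
            sent_index = s + 1  # span 0 is the title
            in_sent = [m for m in by_pos if sent_of.get(m.entity_id) == sent_index]
            chem_m = next(m for m in in_sent if m.surface == chem and m.is_chemical)
            gene_m = next(m for m in in_sent if m.surface == gene and m.is_gene)
            truth.append(TruthRecord(doc_id, sent_index, chem_m.entity_id,
                                     gene_m.entity_id, label))
            if label != "NEG":
                relations.append(RelationAnnotation(
                    doc_id, label, True, _RELATION_NAMES[label],
                    chem_m.entity_id, gene_m.entity_id))
            elif rng.random() < config.noneval_rate:
                relations.append(RelationAnnotation(
                    doc_id, "CPR:2", False, _RELATION_NAMES["CPR:2"],
                    chem_m.entity_id, gene_m.entity_id))

    corpus = SynthCorpus(documents, mentions, relations, truth, config)
    if out_dir is not None:
        write_synth_corpus(corpus, out_dir)
    return corpus


def generate_hard_corpus(config: SynthConfig, out_dir=None) -> SynthCorpus:
    """The difficult regime: multi-clause and passive sentences, extra
    distractor entities and CPR:3/CPR:4 trigger confounds."""
    hard = replace(
        config,
        passive_rate=max(config.passive_rate, 0.3),
        multi_clause_rate=max(config.multi_clause_rate, 0.4),
        distractor_rate=max(config.distractor_rate, 0.3),
        confound_rate=max(config.confound_rate, 0.5),
    )
    return generate_corpus(hard, out_dir)


def write_synth_corpus(corpus: SynthCorpus, out_dir) -> dict[str, Path]:
    """Write the three TSV files plus a ground-truth JSON-lines file."""
    paths = write_corpus(corpus.documents, corpus.mentions, corpus.relations, out_dir)
    truth_path = Path(out_dir) / "instances.jsonl"
    with open(truth_path, "w", encoding="utf-8") as fh:
        for t in corpus.truth:
            fh.write(json.dumps(vars(t)) + "\n")
    paths["truth"] = truth_path
    return paths


def keyword_baseline(tokens, lexicon: dict[str, tuple[str, ...]] | None = None) -> str:
    """Label a token list by trigger-keyword lookup (NEG if none found).

    With disjoint lexicons, trigger strength 1 and no confounds this is
    the Bayes-optimal classifier for the generated corpora.
    """
    lexicon = lexicon if lexicon is not None else DEFAULT_TRIGGERS
    lookup = {w: c for c, words in lexicon.items() for w in words}
    for tok in tokens:
        hit = lookup.get(str(tok).lower())
        if hit is not None:
            return hit
    return "NEG"
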