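"""Tokenization, POS tagging, position features and index mapping.

The classifier consumes, per candidate instance, four aligned integer
sequences: token ids, coarse POS-tag ids, and two channels of clipped
token distances to the chemical and to the gene mention.  Distances are
0 on the mention itself, negative before it and positive after it,
clipped to [-D, D] and shifted by +D so they can index an embedding
table.

Tokenization is mention-boundary-aware: a gold entity mention is always
emitted as a single token, so character offsets from the annotation
files map cleanly onto token positions.  The POS tagger is a pluggable
dependency; the default is a deterministic regex-based coarse tagger so
the pipeline needs no model downloads.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .corpus import LABELS, LABEL_TO_ID, CandidateInstance, Document, EntityMention

PAD, OOV = "<PAD>", "<OOV>"
CHEM_PLACEHOLDER, GENE_PLACEHOLDER, OTHER_PLACEHOLDER = (
    "CHEM_ENT",
    "GENE_ENT",
    "ENT_OTHER",
)
PLACEHOLDERS = frozenset({CHEM_PLACEHOLDER, GENE_PLACEHOLDER, OTHER_PLACEHOLDER})

# Coarse POS tag inventory for the fallback tagger.
_DETS = {"the", "a", "an", "this", "that", "these", "those"}
_ADPS = {"in", "of", "by", "on", "at", "with", "from", "to", "for", "via",
         "through", "into", "between", "against"}
_CONJ = {"and", "or", "but", "whereas", "while", "although"}
_VERBS = {"is", "are", "was", "were", "be", "been", "has", "have", "had",
          "does", "do", "did", "can", "may", "binds", "acts", "shows"}


def coarse_pos_tag(token: str) -> str:
    """Deterministic regex/lexicon coarse POS tagger (no downloads)."""
    low = token.lower()
    if token in PLACEHOLDERS:
        return "NOUN"
    if re.fullmatch(r"[0-9]+([.,][0-9]+)?", low):
        return "NUM"
    if not any(ch.isalnum() for ch in token):
        return "PUNCT"
    if low in _DETS:
        return "DET"
    if low in _ADPS:
        return "ADP"
    if low in _CONJ:
        return "CONJ"
    if low in _VERBS or low.endswith(("ed", "ing", "izes", "ates", "ysed")):
        return "VERB"
    if low.endswith("ly"):
        return "ADV"
    return "NOUN"


@dataclass(frozen=True)
class TokenRecord:
    text: str
    pos_tag: str
    char_span: tuple[int, int]  # within the sentence


_WORD = re.compile(r"\w+|[^\w\s]")


def tokenize_and_tag(
    sentence: str,
    mention_spans: Sequence[tuple[int, int]] = (),
    tagger: Callable[[str], str] = coarse_pos_tag,
) -> list[TokenRecord]:
    """Tokenize one sentence, keeping each gold mention a single token.

    ``mention_spans`` are (start, end) offsets relative to the sentence.
    Outside mentions, maximal ``\\w+`` runs and single punctuation marks
    are tokens.  Raises on an empty sentence.
    """
    if not sentence or not sentence.strip():
        raise ValueError("cannot tokenize an empty sentence")
    spans = sorted(set((s, e) for s, e in mention_spans if e > s))
    # drop mention spans nested inside an earlier one
    kept: list[tuple[int, int]] = []
    for s, e in spans:
        if kept and s < kept[-1][1]:
            continue
        kept.append((s, e))

    tokens: list[TokenRecord] = []

    def add_plain(seg_start: int, seg_end: int) -> None:
        for m in _WORD.finditer(sentence, seg_start, seg_end):
            tokens.append(TokenRecord(m.group(), tagger(m.group()), (m.start(), m.end())))

    cursor = 0
    for s, e in kept:
        add_plain(cursor, s)
        surface = sentence[s:e]
        tokens.append(TokenRecord(surface, tagger(surface), (s, e)))
        cursor = e
    add_plain(cursor, len(sentence))
    return tokens


def token_range_for_span(
    tokens: Sequence[TokenRecord], span: tuple[int, int]
) -> tuple[int, int]:
    """Inclusive token index range [s, e] covering a character span."""
    s_char, e_char = span
    covered = [
        i for i, t in enumerate(tokens)
        if t.char_span[1] > s_char and t.char_span[0] < e_char
    ]
    if not covered:
        raise ValueError(f"entity span {span} not found among tokens")
    return covered[0], covered[-1]


def relative_positions(
    n_tokens: int, token_range: tuple[int, int], clip: int = 30
) -> np.ndarray:
    """Signed, clipped token distances to an entity (head-span convention).

    0 on the entity tokens, ``i - s`` before it (negative), ``i - e``
    after it (positive), clipped to [-clip, clip].
    """
    s, e = token_range
    if not (0 <= s <= e < n_tokens):
        raise ValueError(f"token range {token_range} outside 0..{n_tokens - 1}")
    idx = np.arange(n_tokens)
    out = np.where(idx < s, idx - s, np.where(idx > e, idx - e, 0))
    return np.clip(out, -clip, clip)


class Vocabulary:
    """Dense string-to-index map with reserved PAD (0) and OOV (1)."""

    def __init__(self, reserved: tuple[str, str] = (PAD, OOV)):
        self.pad_token, self.oov_token = reserved
        self.token_to_index: dict[str, int] = {
            self.pad_token: 0,
            self.oov_token: 1,
        }
        self.frozen = False

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def oov_index(self) -> int:
        return 1

    def add(self, token: str) -> int:
        if token in self.token_to_index:
            return self.token_to_index[token]
        if self.frozen:
            return self.oov_index
        idx = len(self.token_to_index)
        self.token_to_index[token] = idx
        return idx

    def lookup(self, token: str) -> int:
        return self.token_to_index.get(token, self.oov_index)

    def freeze(self) -> "Vocabulary":
        self.frozen = True
        return self

    @property
    def index_to_token(self) -> list[str]:
        out = [""] * len(self.token_to_index)
        for tok, i in self.token_to_index.items():
            out[i] = tok
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"tokens": self.index_to_token, "frozen": self.frozen},
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        payload = json.loads(text)
        vocab = cls()
        for tok in payload["tokens"][2:]:
            vocab.add(tok)
        vocab.frozen = payload["frozen"]
        return vocab


@dataclass
class FeaturizedInstance:
    """Aligned index sequences for one candidate pair."""

    token_ids: np.ndarray
    pos_tag_ids: np.ndarray
    dist_chem: np.ndarray  # clipped distance + D (non-negative)
    dist_gene: np.ndarray
    label_id: int
    tokens: list[str] = field(default_factory=list)  # post-anonymization text
    doc_id: str = ""
    sentence_index: int = -1

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def sentence_key(self) -> tuple[int, ...]:
        return tuple(int(i) for i in self.token_ids)


def prepare_tokens(
    instance: CandidateInstance,
    doc: Document,
    doc_mentions: Iterable[EntityMention] = (),
    anonymize: str = "targets",
    tagger: Callable[[str], str] = coarse_pos_tag,
) -> tuple[list[TokenRecord], tuple[int, int], tuple[int, int]]:
    """Tokenize the instance sentence and locate the two target entities.

    ``anonymize`` is one of ``none`` (keep surfaces), ``targets``
    (replace the two target mentions with CHEM_ENT / GENE_ENT; the
    default, so the model cannot memorize entity names) or ``all``
    (additionally replace every other annotated mention with ENT_OTHER).

    Returns (tokens, chem token range, gene token range).
    """
    if anonymize not in ("none", "targets", "all"):
        raise ValueError(f"unknown anonymization policy {anonymize!r}")
    sent_start, sent_end = doc.sentence_spans[instance.sentence_index]
    sentence = doc.full_text[sent_start:sent_end]

    others = [
        (m.char_start - sent_start, m.char_end - sent_start)
        for m in doc_mentions
        if m.doc_id == doc.doc_id
        and m.char_start >= sent_start
        and m.char_end <= sent_end
        and m.entity_id not in (instance.chem.entity_id, instance.gene.entity_id)
    ]
    chem_span = (
        instance.chem.char_start - sent_start,
        instance.chem.char_end - sent_start,
    )
    gene_span = (
        instance.gene.char_start - sent_start,
        instance.gene.char_end - sent_start,
    )
    tokens = tokenize_and_tag(sentence, [chem_span, gene_span] + others, tagger)
    chem_range = token_range_for_span(tokens, chem_span)
    gene_range = token_range_for_span(tokens, gene_span)

    if anonymize != "none":
        replaced = []
        other_set = set(others)
        for i, tok in enumerate(tokens):
            if chem_range[0] <= i <= chem_range[1]:
                text = CHEM_PLACEHOLDER
            elif gene_range[0] <= i <= gene_range[1]:
                text = GENE_PLACEHOLDER
            elif anonymize == "all" and tok.char_span in other_set:
                text = OTHER_PLACEHOLDER
            else:
                text = tok.text
            replaced.append(TokenRecord(text, tagger(text), tok.char_span))
        tokens = replaced
    return tokens, chem_range, gene_range


def featurize(
    instance: CandidateInstance,
    doc: Document,
    token_vocab: Vocabulary,
    pos_vocab: Vocabulary,
    clip_distance: int = 30,
    doc_mentions: Iterable[EntityMention] = (),
    anonymize: str = "targets",
    tagger: Callable[[str], str] = coarse_pos_tag,
) -> FeaturizedInstance:
    """Map a candidate instance to aligned index sequences.

    Pure function of (instance, vocabularies, clip distance): building
    it twice yields identical arrays.
    """
    if instance.label not in LABELS:
        raise ValueError(f"label {instance.label!r} outside the 6-class set")
    tokens, chem_range, gene_range = prepare_tokens(
        instance, doc, doc_mentions, anonymize, tagger
    )
    n = len(tokens)
    token_ids = np.array([token_vocab.add(t.text) for t in tokens], dtype=np.int64)
    pos_ids = np.array([pos_vocab.add(t.pos_tag) for t in tokens], dtype=np.int64)
    d_chem = relative_positions(n, chem_range, clip_distance) + clip_distance
    d_gene = relative_positions(n, gene_range, clip_distance) + clip_distance
    return FeaturizedInstance(
        token_ids=token_ids,
        pos_tag_ids=pos_ids,
        dist_chem=d_chem.astype(np.int64),
        dist_gene=d_gene.astype(np.int64),
        label_id=LABEL_TO_ID[instance.label],
        tokens=[t.text for t in tokens],
        doc_id=instance.doc_id,
        sentence_index=instance.sentence_index,
    )


@dataclass
class Batch:
    """A padded mini-batch with a boolean mask of real positions."""

    token_ids: np.ndarray  # (B, T) int
    pos_tag_ids: np.ndarray
    dist_chem: np.ndarray
    dist_gene: np.ndarray
    mask: np.ndarray  # (B, T) bool
    labels: np.ndarray  # (B,) int
    lengths: np.ndarray  # (B,) int
    instances: list[FeaturizedInstance] = field(default_factory=list)

    def __len__(self) -> int:
        return self.token_ids.shape[0]


def pad_batch(instances: Sequence[FeaturizedInstance]) -> Batch:
    """Pad a list of featurized instances to a common length with PAD=0."""
    if not instances:
        raise ValueError("cannot pad an empty batch")
    lengths = np.array([len(f) for f in instances], dtype=np.int64)
    T = int(lengths.max())
    B = len(instances)

    def padded(attr: str) -> np.ndarray:
        out = np.zeros((B, T), dtype=np.int64)
        for i, f in enumerate(instances):
            seq = getattr(f, attr)
            out[i, : len(seq)] = seq
        return out

    mask = np.arange(T)[None, :] < lengths[:, None]
    return Batch(
        token_ids=padded("token_ids"),
        pos_tag_ids=padded("pos_tag_ids"),
        dist_chem=padded("dist_chem"),
        dist_gene=padded("dist_gene"),
        mask=mask,
        labels=np.array([f.label_id for f in instances], dtype=np.int64),
        lengths=lengths,
        instances=list(instances),
    )


def iter_batches(
    instances: Sequence[FeaturizedInstance],
    batch_size: int,
    rng: np.random.Generator | None = None,
):
    """Yield padded batches, optionally in a seeded shuffled order."""
    order = np.arange(len(instances))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(order), batch_size):
        chunk = [instances[i] for i in order[start : start + batch_size]]
        yield pad_batch(chunk)
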