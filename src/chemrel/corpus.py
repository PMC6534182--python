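"""ChemProt-format corpus I/O and candidate-pair generation.

A ChemProt-style corpus is distributed as three headerless, tab-separated
UTF-8 files:

* abstracts: ``doc_id \\t title \\t abstract``
* entities:  ``doc_id \\t entity_id \\t type \\t start \\t end \\t text``
  with type one of CHEMICAL, GENE-Y, GENE-N
* relations: ``doc_id \\t cpr_class \\t eval_flag \\t relation_name \\t
  Arg1:Tx \\t Arg2:Ty``

Character offsets are 0-based half-open over ``full_text`` = title +
``"\\t"`` + abstract (the separator is configurable but a single tab is
the convention this package reads and writes).

Relation classes follow the CPR scheme: ten classes CPR:1..CPR:10 of
which five are evaluated (CPR:3 up-regulator/activator, CPR:4
down-regulator/inhibitor, CPR:5 agonist, CPR:6 antagonist, CPR:9
substrate/product-of).  Classification operates on within-sentence
(chemical, gene) candidate pairs; a pair carrying no evaluated gold
relation is a negative instance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

# Fixed 6-way label order used everywhere (featurization, model output,
# confusion matrices).
LABELS = ("NEG", "CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")
LABEL_TO_ID = {lab: i for i, lab in enumerate(LABELS)}
EVALUATED_CLASSES = frozenset(("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9"))
ALL_CPR_CLASSES = frozenset(f"CPR:{i}" for i in range(1, 11))
ENTITY_TYPES = frozenset(("CHEMICAL", "GENE-Y", "GENE-N"))
TITLE_SEPARATOR = "\t"


class CorpusError(ValueError):
    """Malformed or inconsistent corpus content."""


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    separator: str = TITLE_SEPARATOR
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + self.separator + self.abstract

    def sentence_text(self, index: int) -> str:
        s, e = self.sentence_spans[index]
        return self.full_text[s:e]


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    entity_id: str
    category: str  # CHEMICAL | GENE-Y | GENE-N
    char_start: int
    char_end: int
    surface: str

    @property
    def is_chemical(self) -> bool:
        return self.category == "CHEMICAL"

    @property
    def is_gene(self) -> bool:
        return self.category in ("GENE-Y", "GENE-N")


@dataclass(frozen=True)
class RelationAnnotation:
    doc_id: str
    cpr_class: str
    evaluated: bool
    relation_name: str
    arg1: str
    arg2: str


@dataclass
class CandidateInstance:
    """One within-sentence (chemical, gene) pair to classify."""

    doc_id: str
    sentence_index: int
    chem: EntityMention
    gene: EntityMention
    label: str  # one of LABELS
    tokens: list = field(default_factory=list)  # filled by featurization

    @property
    def label_id(self) -> int:
        return LABEL_TO_ID[self.label]


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "fig", "figs", "et al", "al", "vs", "cf",
    "dr", "no", "approx", "ca", "resp",
}
_BOUNDARY = re.compile(r"[.?!]+(?=\s)")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans (0-based, half-open) over ``text``.

    Splits after ``.?!`` followed by whitespace, with a guard against
    common abbreviations and single-letter initials.  A tab always forces
    a boundary (it separates title from abstract in ``full_text``).
    """
    spans: list[tuple[int, int]] = []
    start = 0

    def flush(end: int) -> None:
        nonlocal start
        seg_start, seg_end = start, end
        while seg_start < seg_end and text[seg_start].isspace():
            seg_start += 1
        while seg_end > seg_start and text[seg_end - 1].isspace():
            seg_end -= 1
        if seg_end > seg_start:
            spans.append((seg_start, seg_end))
        start = end

    for m in _BOUNDARY.finditer(text):
        prev = text[start : m.start()]
        last_word = prev.rsplit(None, 1)[-1].lstrip("([{") if prev.split() else ""
        if last_word.lower().rstrip(".") in _ABBREVIATIONS:
            continue
        if len(last_word) == 1 and last_word.isupper():
            continue  # initial like "E."
        flush(m.end())
    flush(len(text))

    # tab (title/abstract separator) forces boundaries
    final: list[tuple[int, int]] = []
    for s, e in spans:
        seg = text[s:e]
        pos = s
        for part in seg.split("\t"):
            if part.strip():
                p0 = pos + (len(part) - len(part.lstrip()))
                final.append((p0, p0 + len(part.strip())))
            pos += len(part) + 1
    return final


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_tsv(path, n_fields: int, what: str) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise CorpusError(
                    f"{what} line {lineno}: expected {n_fields} tab-separated "
                    f"fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    return rows


def read_corpus(
    abstracts_path,
    entities_path,
    relations_path,
    *,
    split_sentences_fn=split_sentences,
):
    """Parse and validate a three-file ChemProt-style corpus.

    Returns ``(documents, mentions, relations)``.  Every entity offset is
    validated against the reconstructed full text; every relation argument
    must resolve to a known mention of the same document.  All problems
    are collected and raised together in a single :class:`CorpusError`.
    """
    documents: list[Document] = []
    by_id: dict[str, Document] = {}
    for lineno, (doc_id, title, abstract) in _read_tsv(abstracts_path, 3, "abstracts"):
        if doc_id in by_id:
            raise CorpusError(f"abstracts line {lineno}: duplicate doc_id {doc_id}")
        doc = Document(doc_id, title, abstract)
        doc.sentence_spans = split_sentences_fn(doc.full_text)
        documents.append(doc)
        by_id[doc_id] = doc

    errors: list[str] = []
    mentions: list[EntityMention] = []
    for lineno, (doc_id, ent_id, category, start, end, surface) in _read_tsv(
        entities_path, 6, "entities"
    ):
        if category not in ENTITY_TYPES:
            errors.append(f"entities line {lineno}: unknown type {category!r}")
            continue
        if doc_id not in by_id:
            errors.append(f"entities line {lineno}: unknown doc_id {doc_id}")
            continue
        s, e = int(start), int(end)
        if not s < e:
            errors.append(
                f"entities line {lineno}: empty span for {doc_id}/{ent_id}"
            )
            continue
        snippet = by_id[doc_id].full_text[s:e]
        if snippet != surface:
            errors.append(
                f"offset/surface mismatch for doc {doc_id} entity {ent_id}: "
                f"text[{s}:{e}] == {snippet!r} but file says {surface!r}"
            )
            continue
        mentions.append(EntityMention(doc_id, ent_id, category, s, e, surface))

    known = {(m.doc_id, m.entity_id) for m in mentions}
    relations: list[RelationAnnotation] = []
    for lineno, (doc_id, cpr, flag, name, a1, a2) in _read_tsv(
        relations_path, 6, "relations"
    ):
        if cpr not in ALL_CPR_CLASSES:
            raise CorpusError(f"relations line {lineno}: unknown CPR class {cpr!r}")
        arg1 = a1.split(":", 1)[1] if ":" in a1 else a1
        arg2 = a2.split(":", 1)[1] if ":" in a2 else a2
        for arg in (arg1, arg2):
            if (doc_id, arg) not in known:
                errors.append(
                    f"relations line {lineno}: argument {arg} not an entity of "
                    f"doc {doc_id}"
                )
        relations.append(
            RelationAnnotation(doc_id, cpr, flag.strip().upper().startswith("Y"), name, arg1, arg2)
        )

    if errors:
        raise CorpusError("corpus validation failed:\n" + "\n".join(errors))
    return documents, mentions, relations


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_corpus(documents, mentions, relations, out_dir) -> dict[str, Path]:
    """Serialize a corpus back to the three-file TSV dialect.

    Canonical field order matches :func:`read_corpus`, so parse-write is
    an identity on corpora already in canonical form.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": out_dir / "abstracts.tsv",
        "entities": out_dir / "entities.tsv",
        "relations": out_dir / "relations.tsv",
    }
    with open(paths["abstracts"], "w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.entity_id}\t{m.category}\t{m.char_start}\t"
                f"{m.char_end}\t{m.surface}\n"
            )
    with open(paths["relations"], "w", encoding="utf-8") as fh:
        for r in relations:
            flag = "Y" if r.evaluated else "N"
            fh.write(
                f"{r.doc_id}\t{r.cpr_class}\t{flag}\t{r.relation_name}\t"
                f"Arg1:{r.arg1}\tArg2:{r.arg2}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    """Bookkeeping from candidate generation (dropped/skipped gold)."""

    n_instances: int = 0
    cross_sentence_relations: int = 0
    boundary_spanning_entities: int = 0
    warnings: list[str] = field(default_factory=list)


def _sentence_of(doc: Document, mention: EntityMention) -> int | None:
    for i, (s, e) in enumerate(doc.sentence_spans):
        if mention.char_start >= s and mention.char_end <= e:
            return i
    return None


def generate_candidates(
    doc: Document,
    mentions: Iterable[EntityMention],
    relations: Iterable[RelationAnnotation],
    policy: str = "all-pairs",
    report: CandidateReport | None = None,
) -> list[CandidateInstance]:
    """Enumerate within-sentence (chemical, gene) pairs with gold labels.

    Every chemical x gene pair inside one sentence yields one instance.
    A pair linked by an evaluated gold relation is labeled with that CPR
    class (one instance per distinct class if a pair is multi-labeled);
    gold relations of non-evaluated classes and unlinked pairs are NEG.
    Cross-sentence gold relations are dropped and counted in ``report``;
    an entity overlapping a sentence boundary is skipped with a warning.
    """
    if policy != "all-pairs":
        raise ValueError(f"unknown pairing policy {policy!r}")
    report = report if report is not None else CandidateReport()

    doc_mentions = [m for m in mentions if m.doc_id == doc.doc_id]
    sentence_of: dict[str, int] = {}
    for m in doc_mentions:
        sent = _sentence_of(doc, m)
        if sent is None:
            report.boundary_spanning_entities += 1
            report.warnings.append(
                f"entity {m.entity_id} of doc {doc.doc_id} spans a sentence "
                "boundary; skipped"
            )
            continue
        sentence_of[m.entity_id] = sent
    by_entity_id = {m.entity_id: m for m in doc_mentions}

    # gold (chem_id, gene_id) -> set of evaluated classes, chem normalized first
    gold: dict[tuple[str, str], set[str]] = {}
    for r in relations:
        if r.doc_id != doc.doc_id:
            continue
        m1, m2 = by_entity_id.get(r.arg1), by_entity_id.get(r.arg2)
        if m1 is None or m2 is None:
            continue
        if m1.is_chemical and m2.is_gene:
            chem, gene = m1, m2
        elif m2.is_chemical and m1.is_gene:
            chem, gene = m2, m1
        else:
            report.warnings.append(
                f"relation {r.cpr_class} in doc {doc.doc_id} does not link a "
                "chemical with a gene; ignored"
            )
            continue
        s_c = sentence_of.get(chem.entity_id)
        s_g = sentence_of.get(gene.entity_id)
        if s_c is None or s_g is None:
            continue
        if s_c != s_g:
            report.cross_sentence_relations += 1
            continue
        if r.cpr_class in EVALUATED_CLASSES:
            gold.setdefault((chem.entity_id, gene.entity_id), set()).add(r.cpr_class)

    instances: list[CandidateInstance] = []
    chems = [m for m in doc_mentions if m.is_chemical and m.entity_id in sentence_of]
    genes = [m for m in doc_mentions if m.is_gene and m.entity_id in sentence_of]
    for chem in chems:
        for gene in genes:
            if sentence_of[chem.entity_id] != sentence_of[gene.entity_id]:
                continue
            classes = gold.get((chem.entity_id, gene.entity_id), {"NEG"})
            for cls in sorted(classes):
                instances.append(
                    CandidateInstance(
                        doc_id=doc.doc_id,
                        sentence_index=sentence_of[chem.entity_id],
                        chem=chem,
                        gene=gene,
                        label=cls,
                    )
                )
    report.n_instances += len(instances)
    return instances
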