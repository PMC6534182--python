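"""Scoring: micro-averaged P/R/F over the five evaluated CPR classes.

The task is 6-way classification (NEG + CPR:3/4/5/6/9) but scored over
the positive classes only: pooled true positives are the diagonal cells
of the positive rows, pooled false positives everything else predicted
as a positive class (including gold-NEG instances), false negatives
symmetric.  F is the harmonic mean of precision and recall; zero
denominators score 0 by convention.  Reports round half-even to three
decimals, the customary printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .corpus import LABELS, LABEL_TO_ID
from .features import PLACEHOLDERS

POSITIVE_CLASSES = LABELS[1:]


def round3(x: float) -> float:
    """Half-even rounding to 3 decimals (report convention)."""
    return float(np.round(x, 3))


@dataclass
class ConfusionMatrix:
    """6x6 counts; rows = gold label, columns = predicted label."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(LABELS), len(LABELS)):
            raise ValueError(f"confusion matrix must be {len(LABELS)}x{len(LABELS)}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, gold, predicted) -> "ConfusionMatrix":
        gold = [g if isinstance(g, (int, np.integer)) else LABEL_TO_ID[g] for g in gold]
        predicted = [
            p if isinstance(p, (int, np.integer)) else LABEL_TO_ID[p] for p in predicted
        ]
        if len(gold) != len(predicted):
            raise ValueError("gold and predicted label lists differ in length")
        n = len(LABELS)
        for v in list(gold) + list(predicted):
            if not 0 <= v < n:
                raise ValueError(f"unknown label id {v}")
        counts = np.zeros((n, n), dtype=np.int64)
        np.add.at(counts, (gold, predicted), 1)
        return cls(counts)

    def support(self, label: str) -> int:
        return int(self.counts[LABEL_TO_ID[label], :].sum())

    # TSV round trip so published matrices can be scored directly.
    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gold\\pred\t" + "\t".join(LABELS) + "\n")
            for i, lab in enumerate(LABELS):
                fh.write(lab + "\t" + "\t".join(map(str, self.counts[i])) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ConfusionMatrix":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        header = lines[0].split("\t")[1:]
        if tuple(header) != LABELS:
            raise ValueError(f"label order {header} != expected {list(LABELS)}")
        counts = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
        for line in lines[1:]:
            fields = line.split("\t")
            counts[LABEL_TO_ID[fields[0]]] = [int(v) for v in fields[1:]]
        return cls(counts)


def per_class_metrics(cm: ConfusionMatrix, label: str):
    """(precision, recall, F, support) for one positive class."""
    if label not in POSITIVE_CLASSES:
        raise ValueError(f"{label!r} is not an evaluated positive class")
    c = LABEL_TO_ID[label]
    tp = cm.counts[c, c]
    pred = cm.counts[:, c].sum()
    gold = cm.counts[c, :].sum()
    precision = tp / pred if pred else 0.0
    recall = tp / gold if gold else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(precision), float(recall), float(f), int(gold)


def micro_metrics(cm: ConfusionMatrix):
    """(precision, recall, F) pooled over the five positive classes.

    NEG is excluded from the positive set but contributes false
    positives (gold NEG predicted positive) and false negatives (gold
    positive predicted NEG).
    """
    pos = [LABEL_TO_ID[c] for c in POSITIVE_CLASSES]
    tp = sum(cm.counts[c, c] for c in pos)
    predicted = sum(cm.counts[:, c].sum() for c in pos)
    gold = sum(cm.counts[c, :].sum() for c in pos)
    precision = tp / predicted if predicted else 0.0
    recall = tp / gold if gold else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(precision), float(recall), float(f)


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    per_class: dict[str, tuple[float, float, float, int]]
    micro: tuple[float, float, float]
    keywords: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix,
                       keywords: dict[str, list[str]] | None = None) -> "EvalReport":
        return cls(
            confusion=cm,
            per_class={c: per_class_metrics(cm, c) for c in POSITIVE_CLASSES},
            micro=micro_metrics(cm),
            keywords=keywords or {},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "micro": {
                    "precision": round3(self.micro[0]),
                    "recall": round3(self.micro[1]),
                    "f_score": round3(self.micro[2]),
                },
                "per_class": {
                    c: {
                        "support": s,
                        "precision": round3(p),
                        "recall": round3(r),
                        "f_score": round3(f),
                    }
                    for c, (p, r, f, s) in self.per_class.items()
                },
                "confusion": self.confusion.counts.tolist(),
                "keywords": self.keywords,
            },
            indent=2,
        )

    def render(self) -> str:
        lines = ["Label    Support  Precision  Recall  F-score"]
        for c, (p, r, f, s) in self.per_class.items():
            lines.append(f"{c:<8} {s:>7}  {round3(p):>9.3f}  {round3(r):>6.3f}  {round3(f):>7.3f}")
        p, r, f = self.micro
        lines.append(
            f"micro    {sum(v[3] for v in self.per_class.values()):>7}  "
            f"{round3(p):>9.3f}  {round3(r):>6.3f}  {round3(f):>7.3f}"
        )
        if self.keywords:
            lines.append("")
            lines.append("Top attention keywords per predicted class:")
            for c, words in self.keywords.items():
                lines.append(f"  {c}: {', '.join(words) if words else '(none)'}")
        return "\n".join(lines)


def attention_keywords(instances, pool_weights, predicted_ids, k: int = 5,
                       aggregate: str = "sum") -> dict[str, list[str]]:
    """Rank tokens by pooled attention weight within each predicted class.

    ``pool_weights[i]`` is the pooling weight vector (true length) of
    ``instances[i]``; tokens are lowercased, entity placeholders and PAD
    excluded.  ``aggregate`` is ``sum`` (default) or ``mean`` weight per
    token type.  Classes with no predicted instances get an empty list.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    totals: dict[str, dict[str, float]] = {c: {} for c in POSITIVE_CLASSES}
    counts: dict[str, dict[str, int]] = {c: {} for c in POSITIVE_CLASSES}
    for inst, weights, pred in zip(instances, pool_weights, predicted_ids):
        label = LABELS[int(pred)]
        if label not in totals:
            continue
        for tok, w in zip(inst.tokens, weights):
            if tok in PLACEHOLDERS or not tok.strip():
                continue
            low = tok.lower()
            totals[label][low] = totals[label].get(low, 0.0) + float(w)
            counts[label][low] = counts[label].get(low, 0) + 1
    out: dict[str, list[str]] = {}
    for c in POSITIVE_CLASSES:
        scores = totals[c]
        if aggregate == "mean":
            scores = {t: v / counts[c][t] for t, v in scores.items()}
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        out[c] = [t for t, _ in ranked[: max(k, 0)]]
    return out


def load_reference_confusion() -> ConfusionMatrix:
    """Published test-set confusion matrix of a contextualized-attention
    CPI extractor on ChemProt — the scorer's worked example."""
    ref = resources.files("chemrel").joinpath("data/chemprot_test_confusion.tsv")
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_tsv(Path(path))
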