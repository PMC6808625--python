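"""Entity-level scoring in the CoNLL style.

An entity counts as a true positive only when both its label and its exact
character span match a gold entity (strict matching, the CoNLL-2003
criterion); precision/recall/F1 are micro-averaged over labels, and token
accuracy counts every token including O.  Matching is done on character
offsets rather than token indices so that predictions produced under a
different tokenization can still be scored.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_io import entities_to_tags
from .types import Document


@dataclass
class LabelScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    accuracy: Optional[float]  # % tokens correctly tagged; None if untaggable
    overall: LabelScore
    per_label: Dict[str, LabelScore] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def row(s: LabelScore) -> dict:
            return {"tp": s.tp, "fp": s.fp, "fn": s.fn,
                    "precision": s.precision, "recall": s.recall, "f1": s.f1}
        return {
            "accuracy": self.accuracy,
            "overall": row(self.overall),
            "per_label": {k: row(v) for k, v in sorted(self.per_label.items())},
        }


def evaluate(
    gold_docs: Sequence[Document],
    predicted_docs: Sequence[Document],
    scheme: str = "BIOES",
) -> EvalReport:
    """Score predicted documents against gold.

    Documents are paired by doc_id; both sides must cover the same ids.
    Token accuracy additionally requires identical tokenization and is
    reported as None when tokenizations differ.
    """
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in predicted_docs}
    if set(gold_by_id) != set(pred_by_id):
        missing = set(gold_by_id) ^ set(pred_by_id)
        raise ValueError(f"gold/predicted doc_id mismatch: {sorted(missing)}")

    per_label: Dict[str, LabelScore] = {}
    correct_tokens = 0
    total_tokens = 0
    accuracy_ok = True
    for doc_id, gold in gold_by_id.items():
        pred = pred_by_id[doc_id]
        gold_set = {(e.label, e.start, e.end) for e in gold.entities}
        pred_set = {(e.label, e.start, e.end) for e in pred.entities}
        for label, _, _ in gold_set & pred_set:
            per_label.setdefault(label, LabelScore()).tp += 1
        for label, _, _ in pred_set - gold_set:
            per_label.setdefault(label, LabelScore()).fp += 1
        for label, _, _ in gold_set - pred_set:
            per_label.setdefault(label, LabelScore()).fn += 1
        same_tok = (
            [(t.start, t.end) for t in gold.tokens]
            == [(t.start, t.end) for t in pred.tokens]
        )
        if same_tok and gold.tokens:
            g_tags = entities_to_tags(gold, scheme, expand_boundaries=True).tags
            p_tags = entities_to_tags(pred, scheme, expand_boundaries=True).tags
            correct_tokens += sum(g == p for g, p in zip(g_tags, p_tags))
            total_tokens += len(g_tags)
        elif gold.tokens:
            accuracy_ok = False

    overall = LabelScore(
        tp=sum(s.tp for s in per_label.values()),
        fp=sum(s.fp for s in per_label.values()),
        fn=sum(s.fn for s in per_label.values()),
    )
    accuracy = (100.0 * correct_tokens / total_tokens
                if accuracy_ok and total_tokens else None)
    return EvalReport(accuracy=accuracy, overall=overall, per_label=per_label)


def evaluate_tag_columns(
    pairs: Sequence[Tuple[List[str], List[str]]], scheme: str = "BIO"
) -> EvalReport:
    """Score (gold tags, predicted tags) column pairs, conlleval-style.

    Each pair is decoded to entity spans over synthetic token offsets, so
    strict span+label matching applies exactly as for documents.
    """
    from .corpus_io import bio_to_entities, _reconstruct_text
    from .types import TagSequence, Token
    gold_docs, pred_docs = [], []
    for i, (gold_tags, pred_tags) in enumerate(pairs):
        if len(gold_tags) != len(pred_tags):
            raise ValueError(f"pair {i}: tag column lengths differ")
        toks = [Token("w", 2 * j, 2 * j + 1) for j in range(len(gold_tags))]
        text = _reconstruct_text(toks)
        for tags, sink in ((gold_tags, gold_docs), (pred_tags, pred_docs)):
            ents = bio_to_entities(toks, TagSequence(scheme, list(tags)), text)
            sink.append(Document(f"seq{i}", text, toks, ents))
    return evaluate(gold_docs, pred_docs, scheme)


def report_format(report: EvalReport) -> str:
    """Fixed-width table: overall row then per-label rows; per-label
    accuracy cells are left blank (accuracy is a corpus-level quantity)."""
    lines = [f"{'':<18}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1':>9}"]
    acc = f"{report.accuracy:.2f}" if report.accuracy is not None else "-"
    s = report.overall
    lines.append(
        f"{'Overall':<18}{acc:>10}{s.precision:>11.2f}{s.recall:>9.2f}"
        f"{s.f1:>9.2f}"
    )
    for label in sorted(report.per_label):
        s = report.per_label[label]
        lines.append(
            f"{label:<18}{'-':>10}{s.precision:>11.2f}{s.recall:>9.2f}"
            f"{s.f1:>9.2f}"
        )
    return "\n".join(lines)


def report_json(report: EvalReport) -> str:
    return json.dumps(report.to_dict(), indent=1)
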