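"""Micro-averaged precision/recall/F1 scoring of the cascade's outputs.

Relations are scored at four increasingly strict levels — matching the
identifier pair only; pair plus relation type; pair plus novelty flag; and
all three together — with counts pooled over documents (micro-averaging).
Entity mentions are scored strictly on (document, start, end, type), and
linking additionally requires the predicted and gold code sets to
intersect.  All 0/0 ratios are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .documents import Document, RelationInstance

RELATION_LEVELS = ("pair", "pair+relation", "pair+novelty", "all")


@dataclass
class Scores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def add(self, other: "Scores") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass
class EvalReport:
    """Per-level (or per-entity-class) micro scores plus the pooled overall."""

    per_key: dict[str, Scores] = field(default_factory=dict)
    overall: Scores = field(default_factory=Scores)

    def f1(self, key: str | None = None) -> float:
        return (self.per_key[key] if key else self.overall).f1

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            **{k: s.as_dict() for k, s in self.per_key.items()},
        }


def _pair_docs(gold: Sequence[Document], pred: Sequence[Document]):
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in pred}
    if set(gold_by_id) != set(pred_by_id):
        missing = set(gold_by_id) ^ set(pred_by_id)
        raise ValueError(f"gold/pred document ids differ: {sorted(missing)}")
    for doc_id in gold_by_id:
        yield gold_by_id[doc_id], pred_by_id[doc_id]


def _relation_key(r: RelationInstance, level: str):
    if level == "pair":
        return r.pair
    if level == "pair+relation":
        return (r.pair, r.relation_type)
    if level == "pair+novelty":
        return (r.pair, r.novelty)
    if level == "all":
        return (r.pair, r.relation_type, r.novelty)
    raise ValueError(f"unknown level {level!r}; expected one of {RELATION_LEVELS}")


def _score_sets(gold_keys: set, pred_keys: set) -> Scores:
    return Scores(
        tp=len(gold_keys & pred_keys),
        fp=len(pred_keys - gold_keys),
        fn=len(gold_keys - pred_keys),
    )


def eval_relations(
    gold: Sequence[Document], pred: Sequence[Document], levels: Iterable[str] = RELATION_LEVELS
) -> EvalReport:
    """Micro P/R/F1 of predicted relations at the requested levels."""
    report = EvalReport(per_key={lv: Scores() for lv in levels})
    for g, p in _pair_docs(gold, pred):
        for lv in report.per_key:
            s = _score_sets(
                {_relation_key(r, lv) for r in g.relations},
                {_relation_key(r, lv) for r in p.relations},
            )
            report.per_key[lv].add(s)
    report.overall = report.per_key.get("all", Scores())
    return report


def eval_ner(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """Strict span+type mention matching, micro per entity class and overall."""
    report = EvalReport()
    for g, p in _pair_docs(gold, pred):
        classes = {m.entity_type for m in g.mentions} | {m.entity_type for m in p.mentions}
        for cls in classes:
            s = _score_sets(
                {(m.start, m.end) for m in g.mentions if m.entity_type == cls},
                {(m.start, m.end) for m in p.mentions if m.entity_type == cls},
            )
            report.per_key.setdefault(cls, Scores()).add(s)
            report.overall.add(s)
    return report


def eval_linking(gold: Sequence[Document], pred: Sequence[Document]) -> EvalReport:
    """As NER, but a true positive additionally needs a code-set intersection."""
    report = EvalReport()
    for g, p in _pair_docs(gold, pred):
        classes = {m.entity_type for m in g.mentions} | {m.entity_type for m in p.mentions}
        for cls in classes:
            gold_by_span = {
                (m.start, m.end): m.codes for m in g.mentions if m.entity_type == cls
            }
            pred_by_span = {
                (m.start, m.end): m.codes for m in p.mentions if m.entity_type == cls
            }
            s = Scores()
            for span, codes in pred_by_span.items():
                if span in gold_by_span and codes & gold_by_span[span]:
                    s.tp += 1
                else:
                    s.fp += 1
            s.fn = len(gold_by_span) - s.tp
            report.per_key.setdefault(cls, Scores()).add(s)
            report.overall.add(s)
    return report
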