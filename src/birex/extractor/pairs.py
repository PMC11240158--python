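"""Entity grouping and candidate-pair generation for relation extraction.

Relations hold between linked entities, not mention spans: all mentions of
a document sharing a knowledge-base code form one :class:`EntityGroup`, and
candidate pairs are unordered pairs of distinct groups.  Relations are
symmetric, so pairs are canonicalised lexicographically by identifier and
each pair exists exactly once regardless of construction order.  A ninth
"negative" relation class (index 8) marks pairs without a relation so that
detection and classification happen in a single classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from ..documents import RELATION_TYPES, Document, EntityMention, canonical_pair

logger = logging.getLogger(__name__)

NEGATIVE_CLASS = 8
N_RELATION_CLASSES = len(RELATION_TYPES) + 1  # eight relation types + negative

# The eight entity-type combinations that carry relations in the corpus.
DEFAULT_TYPE_PAIRS = frozenset(
    frozenset(p)
    for p in [
        ("Disease", "Gene"),
        ("Chemical", "Gene"),
        ("Disease", "Variant"),
        ("Gene", "Gene"),
        ("Chemical", "Disease"),
        ("Chemical", "Chemical"),
        ("Chemical", "Variant"),
        ("Variant", "Variant"),
    ]
)


@dataclass(frozen=True)
class EntityGroup:
    identifier: str
    entity_type: str
    mentions: tuple[EntityMention, ...]

    def __post_init__(self) -> None:
        if not self.mentions:
            raise ValueError("entity group must have at least one mention")


@dataclass
class CandidatePair:
    """Unordered pair of entity groups with optional training labels.

    ``relation_label`` is an index into the eight relation types, or 8 for
    the negative (no-relation) class; ``novelty_label`` is defined only for
    non-negative pairs.
    """

    groups: tuple[EntityGroup, EntityGroup]
    relation_label: int | None = None
    novelty_label: int | None = None

    def __post_init__(self) -> None:
        a, b = self.groups
        if a.identifier > b.identifier:
            self.groups = (b, a)
        if self.relation_label == NEGATIVE_CLASS and self.novelty_label is not None:
            raise ValueError("negative pairs carry no novelty label")

    @property
    def key(self) -> tuple[str, str]:
        return (self.groups[0].identifier, self.groups[1].identifier)


def group_entities(doc: Document) -> list[EntityGroup]:
    """One group per (code, type); unresolved (code-less) mentions are skipped."""
    grouped: dict[tuple[str, str], list[EntityMention]] = {}
    skipped = 0
    for m in doc.mentions:
        if not m.codes:
            skipped += 1
            continue
        for code in sorted(m.codes):
            grouped.setdefault((code, m.entity_type), []).append(m)
    if skipped:
        logger.info("%s: skipped %d unresolved mentions", doc.doc_id, skipped)
    return [
        EntityGroup(code, etype, tuple(ms))
        for (code, etype), ms in sorted(grouped.items())
    ]


def generate_pairs(
    groups: Sequence[EntityGroup],
    allowed_type_pairs: frozenset[frozenset[str]] | None = DEFAULT_TYPE_PAIRS,
) -> list[CandidatePair]:
    """All unordered pairs of distinct groups with an allowed type combination.

    Pass ``allowed_type_pairs=None`` to allow every combination.
    """
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if a.identifier == b.identifier:
                continue
            tp = frozenset((a.entity_type, b.entity_type))
            if allowed_type_pairs is not None and tp not in allowed_type_pairs:
                continue
            out.append(CandidatePair((a, b)))
    return out


def label_pairs(doc: Document, pairs: Sequence[CandidatePair]) -> None:
    """Attach gold relation/novelty labels in place from the document's relations."""
    gold = {
        canonical_pair(*r.pair): (RELATION_TYPES.index(r.relation_type), int(r.novelty))
        for r in doc.relations
    }
    for p in pairs:
        if p.key in gold:
            p.relation_label, p.novelty_label = gold[p.key]
        else:
            p.relation_label, p.novelty_label = NEGATIVE_CLASS, None
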