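"""Core document model: offset-anchored entity mentions and document-level relations.

A :class:`Document` holds a title and abstract joined by a single space; all
character offsets are 0-based, end-exclusive, and refer to that joined text.
Relations live at the level of knowledge-base identifiers (not mention spans)
and are undirected: identifier pairs are stored in canonical lexicographic
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

ENTITY_TYPES = ("Gene", "Disease", "Chemical", "Variant", "Species", "CellLine")

RELATION_TYPES = (
    "Positive_Correlation",
    "Negative_Correlation",
    "Association",
    "Bind",
    "Drug_Interaction",
    "Cotreatment",
    "Comparison",
    "Conversion",
)


class OffsetIntegrityError(ValueError):
    """A mention's surface text does not match the document slice at its offsets."""


@dataclass(frozen=True)
class EntityMention:
    """A contiguous entity span.

    ``codes`` is the (possibly empty) set of knowledge-base identifiers; it is
    empty before linking.  ``start``/``end`` index ``Document.text``.
    """

    start: int
    end: int
    surface: str
    entity_type: str
    codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"mention span [{self.start}, {self.end}) is empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if "" in self.codes:
            raise ValueError("mention codes may not contain the empty string")
        if not isinstance(self.codes, frozenset):
            object.__setattr__(self, "codes", frozenset(self.codes))

    def with_codes(self, codes: Iterable[str]) -> "EntityMention":
        return replace(self, codes=frozenset(codes))


def canonical_pair(id1: str, id2: str) -> tuple[str, str]:
    """Undirected identifier pair in lexicographic order."""
    return (id1, id2) if id1 <= id2 else (id2, id1)


@dataclass(frozen=True)
class RelationInstance:
    """An undirected relation between two linked entities, with a novelty flag."""

    pair: tuple[str, str]
    relation_type: str
    novelty: bool

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_TYPES:
            raise ValueError(f"unknown relation type {self.relation_type!r}")
        object.__setattr__(self, "pair", canonical_pair(*self.pair))


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space; offsets refer to this."""
        return self.title + " " + self.abstract

    def validate(self) -> None:
        for v in mention_slice_check(self):
            raise OffsetIntegrityError(v)


def mention_slice_check(doc: Document) -> list[str]:
    """Report every mention whose surface disagrees with the text slice.

    Returns human-readable violation strings; an empty list means every
    mention's ``[start, end)`` is in bounds and slices to its surface.  Never
    raises.
    """
    text = doc.text
    violations = []
    for m in doc.mentions:
        if m.start < 0 or m.end > len(text):
            violations.append(
                f"{doc.doc_id}: mention [{m.start}, {m.end}) outside text of length {len(text)}"
            )
        elif text[m.start : m.end] != m.surface:
            violations.append(
                f"{doc.doc_id}: surface {m.surface!r} != text slice "
                f"{text[m.start:m.end]!r} at [{m.start}, {m.end})"
            )
    return violations


def sort_mentions(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    return sorted(mentions, key=lambda m: (m.start, m.end, m.entity_type))
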