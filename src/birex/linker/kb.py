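"""Knowledge-base tables and embedding indexes for entity normalization.

A :class:`KnowledgeBase` is a flat table of ``(code, term, field)`` rows —
``field`` names where the term came from (concept, synonym, definition,
symbol, description, other) — with a lowercase exact-match index.  Gene
tables additionally carry a partition key (the organism's taxonomy code),
since the same symbol names different genes in different species.

Tables read/write as tab-separated text: ``code<TAB>term<TAB>field`` with an
optional fourth partition column.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

TERM_FIELDS = ("concept", "synonym", "definition", "symbol", "description", "other")


@dataclass(frozen=True)
class KBEntry:
    code: str
    term: str
    field: str = "concept"
    partition: str | None = None  # organism code for gene tables


@dataclass
class KnowledgeBase:
    entity_type: str
    entries: list[KBEntry]
    _index: dict[str, set[tuple[str, str | None]]] = dc_field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for e in self.entries:
            self._index.setdefault(e.term.lower(), set()).add((e.code, e.partition))

    def lookup(self, surface: str, partition: str | None = None) -> set[str]:
        """Codes whose indexed terms equal the lowercased surface.

        With ``partition`` given, only entries of that partition (or without
        one) match.
        """
        hits = self._index.get(surface.lower(), set())
        return {
            code
            for code, part in hits
            if partition is None or part is None or part == partition
        }

    def codes(self) -> set[str]:
        return {e.code for e in self.entries}

    def filter_codes(self, keep: Callable[[str], bool]) -> "KnowledgeBase":
        """Sub-table with only the codes accepted by ``keep``."""
        return KnowledgeBase(self.entity_type, [e for e in self.entries if keep(e.code)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                cols = [e.code, e.term, e.field]
                if e.partition is not None:
                    cols.append(e.partition)
                fh.write("\t".join(cols) + "\n")

    @classmethod
    def from_tsv(cls, entity_type: str, path: str | Path) -> "KnowledgeBase":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) not in (3, 4):
                    raise ValueError(f"KB line needs 3 or 4 columns: {line!r}")
                entries.append(KBEntry(cols[0], cols[1], cols[2], cols[3] if len(cols) == 4 else None))
        return cls(entity_type, entries)


def link_exact(surface: str, kb: KnowledgeBase, partition: str | None = None) -> set[str]:
    """Exact (lowercased) dictionary match over the knowledge base."""
    return kb.lookup(surface, partition)


Embedder = Callable[[str], np.ndarray]
"""Maps a surface string to a unit vector; pluggable (tests use a hash encoder)."""


@dataclass
class EmbeddingIndex:
    """Unit-normalised term embeddings for cosine semantic search."""

    codes: list[str]
    vectors: np.ndarray  # (n, d), rows unit-normalised
    partitions: list[str | None] | None = None

    def __post_init__(self) -> None:
        if len(self.codes) != self.vectors.shape[0]:
            raise ValueError("one vector per code required")
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.vectors = self.vectors / norms

    @classmethod
    def build(cls, kb: KnowledgeBase, embedder: Embedder) -> "EmbeddingIndex":
        codes, vecs, parts = [], [], []
        for e in kb.entries:
            codes.append(e.code)
            vecs.append(embedder(e.term))
            parts.append(e.partition)
        d = len(vecs[0]) if vecs else 0
        return cls(codes, np.asarray(vecs).reshape(len(codes), d), parts)


def link_semantic(
    surface_vector: np.ndarray,
    index: EmbeddingIndex,
    threshold: float,
    partition: str | None = None,
) -> tuple[str, float] | None:
    """Best cosine match at or above ``threshold``, else None.

    Ties (within 1e-12) break toward the lexicographically smallest code.
    """
    if index.vectors.shape[0] == 0:
        return None
    q = np.asarray(surface_vector, dtype=float)
    nrm = np.linalg.norm(q)
    if nrm == 0:
        return None
    q = q / nrm
    scores = index.vectors @ q
    if partition is not None and index.partitions is not None:
        keep = np.array(
            [p is None or p == partition for p in index.partitions], dtype=bool
        )
        if not keep.any():
            return None
        scores = np.where(keep, scores, -np.inf)
    best = float(np.max(scores))
    if best < threshold:
        return None
    tied = [c for c, s in zip(index.codes, scores) if s >= best - 1e-12]
    return min(tied), best
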