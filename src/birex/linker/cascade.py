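"""The multi-stage entity-linking cascade with document-level disambiguation.

Stages run in a fixed order per mention — training-dictionary match,
knowledge-base exact match, embedding semantic search — and any mention
left with more than one candidate code is settled by document-level
disambiguation: pick the candidate best supported by the rest of the
document's assignments, on the premise that a document annotates each
concept consistently.  A stage that resolves a mention is final; later
stages never touch it.

Per-type rules mirror the vocabularies' own structure: Species never use
semantic search; Chemical codes are restricted to "D" descriptors and
Disease codes to "C" descriptors plus OMIM; Gene lookups are restricted to
the organism partition chosen by the nearest Species mention in the text
(human, 9606, when no species is mentioned); Variants resolve through
dbSNP lookup keyed by their nearest Gene mention, falling back to tmVar
code generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ..documents import Document, EntityMention
from .kb import Embedder, EmbeddingIndex, KnowledgeBase, link_exact, link_semantic
from .variants import TmvarGenerationError, VariantLookup, generate_tmvar_code

DEFAULT_ORGANISM = "9606"  # human

STAGES = (
    "train_dict",
    "kb_exact",
    "semantic",
    "disambiguated",
    "variant_lookup",
    "tmvar_generated",
    "unresolved",
)


class LinkerConfigError(ValueError):
    pass


@dataclass
class LinkDecision:
    """Outcome of linking one mention, with the stage that produced it."""

    mention: EntityMention
    code: str | None
    stage: str
    score: float = 0.0
    candidates: frozenset[str] = frozenset()  # pending codes before disambiguation

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "unresolved":
            assert self.code is None


@dataclass
class LinkerConfig:
    semantic_threshold: float = 0.70
    per_type_threshold: dict[str, float] = field(default_factory=dict)
    default_organism: str = DEFAULT_ORGANISM

    def threshold(self, entity_type: str) -> float:
        return self.per_type_threshold.get(entity_type, self.semantic_threshold)


TrainDictionary = dict[str, dict[str, frozenset[str]]]  # type -> lowercased surface -> codes


def build_train_dictionary(corpus: Sequence[Document]) -> TrainDictionary:
    """Surface -> code dictionary per entity type from gold training mentions."""
    out: dict[str, dict[str, set[str]]] = {}
    for doc in corpus:
        for m in doc.mentions:
            if not m.codes:
                continue
            out.setdefault(m.entity_type, {}).setdefault(m.surface.lower(), set()).update(
                m.codes
            )
    return {
        etype: {s: frozenset(codes) for s, codes in table.items()}
        for etype, table in out.items()
    }


def nearest_mention(
    anchor: EntityMention, candidates: Sequence[EntityMention]
) -> EntityMention | None:
    """Candidate minimising the character gap to the anchor (0 if overlapping).

    Equidistant candidates break toward the earlier (smaller start) one.
    """
    best = None
    best_key = None
    for c in candidates:
        gap = max(0, max(anchor.start, c.start) - min(anchor.end, c.end))
        key = (gap, c.start)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def disambiguate(decisions: Sequence[LinkDecision]) -> list[LinkDecision]:
    """Resolve multi-candidate mentions by document-level support counting.

    Support for a code is how often it occurs across the document's resolved
    codes plus all candidate sets; each ambiguous mention takes its
    best-supported candidate, ties toward the lexicographically smallest
    code.  Idempotent: resolved decisions pass through untouched.
    """
    support: dict[str, int] = {}
    for d in decisions:
        if d.code is not None:
            support[d.code] = support.get(d.code, 0) + 1
        for c in d.candidates:
            support[c] = support.get(c, 0) + 1
    out = []
    for d in decisions:
        if d.code is not None or not d.candidates:
            out.append(d)
            continue
        top = max(support.get(c, 0) for c in d.candidates)
        best = min(c for c in d.candidates if support.get(c, 0) == top)
        out.append(
            replace(d, code=best, stage="disambiguated", score=1.0, candidates=frozenset())
        )
    return out


def _stage_candidates(
    mention: EntityMention,
    entity_type: str,
    train_dict: TrainDictionary,
    kb: KnowledgeBase | None,
    index: EmbeddingIndex | None,
    embedder: Embedder | None,
    config: LinkerConfig,
    partition: str | None,
    use_semantic: bool,
) -> LinkDecision:
    surface = mention.surface
    codes = train_dict.get(entity_type, {}).get(surface.lower(), frozenset())
    if codes:
        return _decide(mention, codes, "train_dict", 1.0)
    if kb is not None:
        codes = frozenset(link_exact(surface, kb, partition))
        if codes:
            return _decide(mention, codes, "kb_exact", 1.0)
    if use_semantic and index is not None and embedder is not None:
        hit = link_semantic(embedder(surface), index, config.threshold(entity_type), partition)
        if hit is not None:
            code, score = hit
            return LinkDecision(mention, code, "semantic", score)
    return LinkDecision(mention, None, "unresolved")


def _decide(mention: EntityMention, codes: frozenset[str], stage: str, score: float) -> LinkDecision:
    if len(codes) == 1:
        return LinkDecision(mention, next(iter(codes)), stage, score)
    # ambiguous: hold candidates for document-level disambiguation
    return LinkDecision(mention, None, "unresolved", 0.0, candidates=codes)


def normalize_variant(
    mention: EntityMention,
    doc: Document,
    lookup: VariantLookup | None,
    gene_code: str | None,
) -> LinkDecision:
    """dbSNP lookup (surface + nearest gene) first, tmVar generation second."""
    if lookup is not None:
        rs = lookup(mention.surface, gene_code)
        if rs is not None:
            return LinkDecision(mention, rs, "variant_lookup", 1.0)
    try:
        return LinkDecision(mention, generate_tmvar_code(mention.surface), "tmvar_generated", 1.0)
    except TmvarGenerationError:
        return LinkDecision(mention, None, "unresolved")


def link_document(
    doc: Document,
    kbs: Mapping[str, KnowledgeBase],
    indexes: Mapping[str, EmbeddingIndex] | None = None,
    train_dict: TrainDictionary | None = None,
    config: LinkerConfig | None = None,
    embedder: Embedder | None = None,
    variant_lookup: VariantLookup | None = None,
) -> tuple[Document, list[LinkDecision]]:
    """Link every mention of a document; returns a linked copy plus decisions.

    Species are linked first (genes need them), then Genes (variants need
    them), then the remaining types; Variants last.
    """
    config = config or LinkerConfig()
    indexes = indexes or {}
    train_dict = train_dict or {}
    types_present = {m.entity_type for m in doc.mentions}
    for etype in types_present:
        if etype != "Variant" and etype not in kbs:
            raise LinkerConfigError(f"no knowledge base configured for {etype}")

    filtered: dict[str, KnowledgeBase] = dict(kbs)
    if "Chemical" in filtered:
        filtered["Chemical"] = filtered["Chemical"].filter_codes(lambda c: c.startswith("D"))
    if "Disease" in filtered:
        filtered["Disease"] = filtered["Disease"].filter_codes(
            lambda c: c.startswith("C") or c.upper().startswith("OMIM")
        )

    decisions: dict[int, LinkDecision] = {}  # mention position in doc.mentions

    def run_type(etype: str) -> None:
        for i, m in enumerate(doc.mentions):
            if m.entity_type != etype:
                continue
            partition = None
            if etype == "Gene":
                species = [
                    decisions[j].mention.with_codes([decisions[j].code])
                    for j, d in decisions.items()
                    if d.mention.entity_type == "Species" and d.code is not None
                ]
                near = nearest_mention(m, species)
                partition = (
                    next(iter(near.codes)) if near is not None else config.default_organism
                )
            decisions[i] = _stage_candidates(
                m,
                etype,
                train_dict,
                filtered.get(etype),
                indexes.get(etype),
                embedder,
                config,
                partition,
                use_semantic=etype != "Species",
            )

    order = ["Species", "Gene"] + sorted(types_present - {"Species", "Gene", "Variant"})
    for etype in order:
        if etype in types_present:
            run_type(etype)

    if "Variant" in types_present:
        gene_mentions = [
            decisions[j].mention.with_codes([decisions[j].code])
            for j, d in decisions.items()
            if d.mention.entity_type == "Gene" and d.code is not None
        ]
        for i, m in enumerate(doc.mentions):
            if m.entity_type != "Variant":
                continue
            codes = train_dict.get("Variant", {}).get(m.surface.lower(), frozenset())
            if codes:
                decisions[i] = _decide(m, codes, "train_dict", 1.0)
                continue
            near = nearest_mention(m, gene_mentions)
            gene_code = next(iter(near.codes)) if near is not None else None
            decisions[i] = normalize_variant(m, doc, variant_lookup, gene_code)

    ordered = [decisions[i] for i in range(len(doc.mentions))]
    ordered = disambiguate(ordered)

    linked = Document(doc.doc_id, doc.title, doc.abstract, relations=list(doc.relations))
    for m, d in zip(doc.mentions, ordered):
        linked.mentions.append(m.with_codes([d.code] if d.code is not None else []))
    return linked, ordered
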