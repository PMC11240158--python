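"""Seeded synthetic corpora, knowledge bases and a deterministic toy encoder.

Every stage of the cascade is trainable and testable offline: this module
generates small PubMed-abstract-like documents with the six entity classes,
per-mention gold codes, planted relations with novelty flags, matching
knowledge-base tables, embedding indexes and an offline variant lookup.

The construction makes the labels *recoverable by design*: entity surfaces
come from disjoint per-type vocabularies, and each planted relation is
realised as a dedicated sentence ``<relation-trigger> <mention of A>
<novelty-trigger> <mention of B> .`` whose trigger tokens determine the
relation type and novelty flag.  The toy encoder concatenates a per-token
hash embedding with a short moving-average context channel, so both the
tagger (token identity) and the extractor (trigger tokens near the entity
markers) see a linearly recoverable signal.  None of this emulates the
lexical or discourse statistics of real abstracts; it exercises the
machinery, not the science of any particular corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .documents import RELATION_TYPES, Document, EntityMention, RelationInstance
from .encoding import token_to_id
from .extractor.pairs import DEFAULT_TYPE_PAIRS
from .linker.kb import Embedder, EmbeddingIndex, KBEntry, KnowledgeBase
from .linker.variants import DictVariantLookup

# Single-token variant surfaces with hand-written gold codes (surfaces must
# survive word tokenization as one token so BIO spans stay unambiguous).
VARIANT_VOCAB: tuple[tuple[str, str], ...] = (
    ("G203A", "c|SUB|G|203|A"),
    ("R114G", "p|SUB|R|114|G"),
    ("A1188T", "c|SUB|A|1188|T"),
    ("K76M", "p|SUB|K|76|M"),
    ("76delA", "c|DEL|76|A"),
    ("rs5030858", "rs5030858"),
)

SPECIES_VOCAB: tuple[tuple[str, str], ...] = (
    ("human", "9606"),
    ("mouse", "10090"),
    ("rat", "10116"),
    ("zebrafish", "7955"),
)

_FILLER = (
    "we studied the effect of treatment in patients and observed that levels "
    "were altered during analysis"
).split()
_TITLE = "a toy report on planted biomedical relations".split()
_REL_TRIGGERS = tuple(f"linktrig{i}" for i in range(len(RELATION_TYPES)))
_NOV_TRIGGERS = ("knownfact", "newfound")  # index = novelty flag

_TYPE_PREFIX = {
    "Gene": "grx",
    "Disease": "dsx",
    "Chemical": "chx",
    "CellLine": "clx",
}
_CODE_PREFIX = {"Gene": "G", "Disease": "C", "Chemical": "D", "CellLine": "CVCL_"}


@dataclass
class FixtureConfig:
    n_docs: int = 200
    vocab_size: int = 10  # surfaces per generated entity type
    entities_per_doc: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "Gene": (1, 2),
            "Disease": (1, 2),
            "Chemical": (0, 2),
            "Variant": (0, 1),
            "Species": (0, 1),
            "CellLine": (0, 1),
        }
    )
    relation_density: float = 0.45  # P(relation) per allowed co-occurring pair
    novelty_proportion: float = 0.7  # fraction of planted relations that are novel
    ambiguity_rate: float = 0.0  # fraction of KB surfaces carrying a second code
    variant_lookup_coverage: float = 0.34  # fraction of variant surfaces with rs ids
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.relation_density,
            self.novelty_proportion,
            self.ambiguity_rate,
            self.variant_lookup_coverage,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_docs < 0 or self.vocab_size < 1:
            raise ValueError("counts must be non-negative")


class ToyEncoder:
    """Deterministic hash-embedding encoder with a moving-average context channel.

    Each token id maps to a fixed unit vector drawn from a generator seeded
    by (seed, id); the output concatenates that vector with the mean of base
    vectors in a +-``context_window`` token neighbourhood, giving positions a
    little context without any training.  Satisfies the TokenEncoder contract.
    """

    def __init__(self, d_token: int = 128, context_window: int = 3, seed: int = 7):
        self.d_token = d_token
        self.context_window = context_window
        self.seed = seed
        self._cache: dict[int, np.ndarray] = {}

    @property
    def dimension(self) -> int:
        return 2 * self.d_token

    def base_vector(self, token_id: int) -> np.ndarray:
        v = self._cache.get(token_id)
        if v is None:
            rng = np.random.default_rng((self.seed, int(token_id)))
            v = rng.standard_normal(self.d_token)
            v /= np.linalg.norm(v)
            self._cache[token_id] = v
        return v

    def encode(self, token_ids: Sequence[int] | np.ndarray) -> np.ndarray:
        ids = np.asarray(token_ids, dtype=np.int64)
        n = len(ids)
        base = np.empty((n, self.d_token))
        for i, t in enumerate(ids):
            base[i] = self.base_vector(int(t))
        ctx = np.empty_like(base)
        w = self.context_window
        for i in range(n):
            ctx[i] = base[max(0, i - w) : i + w + 1].mean(axis=0)
        return np.concatenate([base, ctx], axis=1)


def toy_surface_embedder(encoder: ToyEncoder) -> Embedder:
    """Surface -> unit vector: mean of token base vectors (hash features)."""
    from .encoding import tokenize

    def embed(surface: str) -> np.ndarray:
        tdoc = tokenize(surface)
        if len(tdoc) == 0:
            return np.zeros(encoder.d_token)
        vecs = np.stack([encoder.base_vector(int(t)) for t in tdoc.token_ids])
        v = vecs.mean(axis=0)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm else v

    return embed


def _surface_table(config: FixtureConfig) -> dict[str, list[tuple[str, str]]]:
    """Per-type (surface, code) vocabularies, deterministic in the config."""
    table: dict[str, list[tuple[str, str]]] = {}
    for etype, prefix in _TYPE_PREFIX.items():
        entries = []
        for i in range(config.vocab_size):
            base = f"{prefix}{i}"
            # a quarter of the surfaces are two-token, with a type-specific modifier
            surface = f"{base} {prefix}form" if i % 4 == 3 else base
            entries.append((surface, f"{_CODE_PREFIX[etype]}{i:03d}"))
        table[etype] = entries
    table["Species"] = list(SPECIES_VOCAB)
    table["Variant"] = [
        (s, c) for s, c in VARIANT_VOCAB
    ]
    n_rs = int(np.ceil(config.variant_lookup_coverage * len(table["Variant"])))
    # the first n_rs variant surfaces are "known to dbSNP": gold code is an rs id
    table["Variant"] = [
        (s, f"rs99{i:04d}" if i < n_rs and not s.startswith("rs") else c)
        for i, (s, c) in enumerate(table["Variant"])
    ]
    return table


def variant_lookup_fixture(config: FixtureConfig) -> DictVariantLookup:
    """Offline dbSNP stand-in covering the configured fraction of variants."""
    table = {}
    for surface, code in _surface_table(config)["Variant"]:
        if code.startswith("rs"):
            table[(surface.lower(), None)] = code
    return DictVariantLookup(table)


class _TextBuilder:
    def __init__(self, title: str):
        self.title = title
        self.words: list[str] = []
        self.mentions: list[tuple[int, int, str, str, str]] = []
        self._pos = len(title) + 1  # offsets over title + " " + abstract

    def add_words(self, words: Sequence[str]) -> None:
        for w in words:
            if self.words:
                self._pos += 1
            self.words.append(w)
            self._pos += len(w)

    def add_mention(self, surface: str, etype: str, code: str) -> None:
        if self.words:
            self._pos += 1
        start = self._pos
        self.words.append(surface)
        self._pos += len(surface)
        self.mentions.append((start, self._pos, surface, etype, code))

    def build(self, doc_id: str) -> Document:
        doc = Document(doc_id, self.title, " ".join(self.words))
        for start, end, surface, etype, code in self.mentions:
            doc.mentions.append(EntityMention(start, end, surface, etype, frozenset([code])))
        return doc


def make_toy_corpus(config: FixtureConfig | None = None) -> list[Document]:
    """Generate gold documents with planted, trigger-determined relations."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    table = _surface_table(config)
    docs = []
    for d in range(config.n_docs):
        builder = _TextBuilder(" ".join(_TITLE))
        chosen: list[tuple[str, str, str]] = []  # (surface, type, code)
        for etype, (lo, hi) in config.entities_per_doc.items():
            k = int(rng.integers(lo, hi + 1))
            if k == 0:
                continue
            picks = rng.choice(len(table[etype]), size=min(k, len(table[etype])), replace=False)
            chosen.extend((table[etype][i][0], etype, table[etype][i][1]) for i in picks)
        rng.shuffle(chosen)

        # one introduction sentence per entity
        for surface, etype, code in chosen:
            lead = list(rng.choice(_FILLER, size=3))
            builder.add_words(lead)
            builder.add_mention(surface, etype, code)
            builder.add_words(["."])

        # plant relations on allowed type pairs of co-occurring entities
        relations = []
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                s1, t1, c1 = chosen[i]
                s2, t2, c2 = chosen[j]
                if c1 == c2 or frozenset((t1, t2)) not in DEFAULT_TYPE_PAIRS:
                    continue
                if rng.random() >= config.relation_density:
                    continue
                r = int(rng.integers(0, len(RELATION_TYPES)))
                novel = bool(rng.random() < config.novelty_proportion)
                builder.add_words([_REL_TRIGGERS[r]])
                builder.add_mention(s1, t1, c1)
                builder.add_words([_NOV_TRIGGERS[int(novel)]])
                builder.add_mention(s2, t2, c2)
                builder.add_words(["."])
                relations.append(RelationInstance((c1, c2), RELATION_TYPES[r], novel))
        doc = builder.build(f"toy{d:04d}")
        doc.relations = relations
        docs.append(doc)
    return docs


def make_toy_kb(
    config: FixtureConfig | None = None, encoder: ToyEncoder | None = None
) -> tuple[dict[str, KnowledgeBase], dict[str, EmbeddingIndex], DictVariantLookup]:
    """Per-type knowledge bases, embedding indexes and the variant lookup.

    Tables are consistent with :func:`make_toy_corpus` under the same config;
    the ambiguity rate adds a second (alternative) code to a deterministic
    fraction of surfaces, to be settled by document-level disambiguation.
    """
    config = config or FixtureConfig()
    encoder = encoder or ToyEncoder()
    rng = np.random.default_rng(config.seed + 1)
    table = _surface_table(config)
    kbs: dict[str, KnowledgeBase] = {}
    for etype, pairs in table.items():
        if etype == "Variant":
            continue
        entries = []
        for surface, code in pairs:
            entries.append(KBEntry(code, surface, "concept"))
            if etype != "Species" and rng.random() < config.ambiguity_rate:
                entries.append(KBEntry(code + "alt", surface, "synonym"))
        kbs[etype] = KnowledgeBase(etype, entries)
    embedder = toy_surface_embedder(encoder)
    indexes = {
        etype: EmbeddingIndex.build(kb, embedder)
        for etype, kb in kbs.items()
        if etype != "Species"
    }
    return kbs, indexes, variant_lookup_fixture(config)
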