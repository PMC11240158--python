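"""Linking cascade: dictionaries, semantic search, disambiguation, gene/species."""

import numpy as np
import pytest

from birex.documents import Document, EntityMention
from birex.fixtures import (
    FixtureConfig,
    ToyEncoder,
    make_toy_corpus,
    make_toy_kb,
    toy_surface_embedder,
)
from birex.linker import (
    EmbeddingIndex,
    KBEntry,
    KnowledgeBase,
    LinkDecision,
    LinkerConfig,
    LinkerConfigError,
    build_train_dictionary,
    disambiguate,
    link_document,
    link_exact,
    link_semantic,
    nearest_mention,
)


def _doc_with(surfaces_types, title="t"):
    """Build a document whose abstract is the surfaces joined by spaces."""
    abstract = " ".join(s for s, _ in surfaces_types)
    doc = Document("d", title, abstract)
    pos = len(title) + 1
    for s, etype in surfaces_types:
        doc.mentions.append(EntityMention(pos, pos + len(s), s, etype))
        pos += len(s) + 1
    return doc


def test_train_dictionary_is_case_insensitive():
    doc = _doc_with([("Glioma", "Disease")])
    doc.mentions[0] = doc.mentions[0].with_codes(["D000001"])
    td = build_train_dictionary([doc])
    assert td["Disease"]["glioma"] == {"D000001"}


def test_train_dictionary_keeps_all_codes_for_ambiguous_surface():
    d1 = _doc_with([("p53", "Gene")])
    d1.mentions[0] = d1.mentions[0].with_codes(["7157"])
    d2 = _doc_with([("p53", "Gene")])
    d2.mentions[0] = d2.mentions[0].with_codes(["22059"])
    td = build_train_dictionary([d1, d2])
    assert td["Gene"]["p53"] == {"7157", "22059"}
    assert build_train_dictionary([]) == {}


def test_exact_match_is_lowercased_and_total():
    kb = KnowledgeBase("Disease", [KBEntry("C01", "Glioma"), KBEntry("C02", "glioma")])
    assert link_exact("GLIOMA", kb) == {"C01", "C02"}
    assert link_exact("absent", kb) == set()


def test_semantic_search_hand_computed_cosines():
    index = EmbeddingIndex(["a", "b", "c"], np.array([[1.0, 0], [0, 1.0], [0.6, 0.8]]))
    code, score = link_semantic(np.array([1.0, 0.0]), index, threshold=0.7)
    assert (code, score) == ("a", pytest.approx(1.0))
    code, score = link_semantic(np.array([0.6, 0.8]), index, threshold=0.7)
    assert code == "c" and score == pytest.approx(1.0)
    assert link_semantic(np.array([-1.0, 0.0]), index, threshold=0.7) is None
    assert link_semantic(np.array([1.0, 0.0]), EmbeddingIndex([], np.zeros((0, 2))), 0.5) is None


def test_semantic_tie_breaks_to_smallest_code():
    index = EmbeddingIndex(["zz", "aa"], np.array([[1.0, 0.0], [1.0, 0.0]]))
    code, _ = link_semantic(np.array([1.0, 0.0]), index, threshold=0.5)
    assert code == "aa"


def _dec(surface, code=None, stage="unresolved", candidates=()):
    m = EntityMention(0, max(len(surface), 1), surface, "Disease")
    return LinkDecision(m, code, stage, 1.0 if code else 0.0, frozenset(candidates))


def test_disambiguation_prefers_document_supported_code():
    decisions = [
        _dec("x", code="A", stage="kb_exact"),
        _dec("y", code="A", stage="kb_exact"),
        _dec("z", candidates={"A", "B"}),
    ]
    out = disambiguate(decisions)
    assert out[2].code == "A" and out[2].stage == "disambiguated"


def test_disambiguation_tie_breaks_lexicographically():
    out = disambiguate([_dec("z", candidates={"B", "A"})])
    assert out[0].code == "A"


def test_disambiguation_is_idempotent():
    decisions = [_dec("x", code="B", stage="kb_exact"), _dec("z", candidates={"A", "B"})]
    once = disambiguate(decisions)
    assert disambiguate(once) == once


def test_nearest_mention_distance_and_tie_break():
    gene = EntityMention(100, 105, "xxxxx", "Gene")
    near = EntityMention(50, 57, "yyyyyyy", "Species")
    far = EntityMention(300, 307, "zzzzzzz", "Species")
    assert nearest_mention(gene, [far, near]) is near
    assert nearest_mention(gene, []) is None
    left = EntityMention(80, 90, "l" * 10, "Species")
    right = EntityMention(115, 125, "r" * 10, "Species")  # both gap 10
    assert nearest_mention(gene, [right, left]) is left


@pytest.fixture(scope="module")
def linked_fixture():
    cfg = FixtureConfig(n_docs=30, seed=11)
    corpus = make_toy_corpus(cfg)
    encoder = ToyEncoder()
    kbs, indexes, lookup = make_toy_kb(cfg, encoder)
    train_dict = build_train_dictionary(corpus)
    embedder = toy_surface_embedder(encoder)
    results = []
    for doc in corpus[20:]:
        stripped = Document(doc.doc_id, doc.title, doc.abstract)
        stripped.mentions = [m.with_codes([]) for m in doc.mentions]
        results.append(
            (doc, *link_document(stripped, kbs, indexes, train_dict, LinkerConfig(), embedder, lookup))
        )
    return results


def test_all_training_surfaces_resolve_at_train_dict_stage(linked_fixture):
    for _, _, decisions in linked_fixture:
        for d in decisions:
            assert d.code is not None
            assert d.stage == "train_dict"


def test_linked_codes_match_gold(linked_fixture):
    for gold, linked, _ in linked_fixture:
        for gm, lm in zip(gold.mentions, linked.mentions):
            assert lm.codes == gm.codes


def test_linking_invariant_to_surface_case(linked_fixture):
    gold, _, _ = linked_fixture[0]
    cfg = FixtureConfig(n_docs=30, seed=11)
    encoder = ToyEncoder()
    kbs, indexes, lookup = make_toy_kb(cfg, encoder)
    train_dict = build_train_dictionary(make_toy_corpus(cfg))
    upper = Document(gold.doc_id, gold.title.upper(), gold.abstract.upper())
    upper.mentions = [
        EntityMention(m.start, m.end, m.surface.upper(), m.entity_type) for m in gold.mentions
    ]
    linked, _ = link_document(
        upper, kbs, indexes, train_dict, LinkerConfig(), toy_surface_embedder(encoder), lookup
    )
    for gm, lm in zip(gold.mentions, linked.mentions):
        assert lm.codes == gm.codes


def test_species_never_reach_semantic_stage():
    kb = KnowledgeBase("Species", [KBEntry("9606", "human")])
    encoder = ToyEncoder()
    embedder = toy_surface_embedder(encoder)
    index = EmbeddingIndex.build(KnowledgeBase("Species", [KBEntry("10090", "marmot")]), embedder)
    doc = _doc_with([("marmot", "Species")])
    _, decisions = link_document(
        doc, {"Species": kb}, {"Species": index}, {}, LinkerConfig(), embedder, None
    )
    # even a perfect semantic match is not consulted for Species
    assert decisions[0].stage == "unresolved" and decisions[0].code is None


def test_gene_without_species_mention_defaults_to_human():
    kb_gene = KnowledgeBase(
        "Gene",
        [KBEntry("100", "tp53", partition="9606"), KBEntry("200", "tp53", partition="10090")],
    )
    kb_species = KnowledgeBase("Species", [KBEntry("9606", "human"), KBEntry("10090", "mouse")])
    doc = _doc_with([("tp53", "Gene")])
    _, decisions = link_document(doc, {"Gene": kb_gene, "Species": kb_species})
    assert decisions[0].code == "100"  # the human-partition entry


def test_gene_resolves_in_nearest_species_partition():
    kb_gene = KnowledgeBase(
        "Gene",
        [KBEntry("100", "tp53", partition="9606"), KBEntry("200", "tp53", partition="10090")],
    )
    kb_species = KnowledgeBase("Species", [KBEntry("9606", "human"), KBEntry("10090", "mouse")])
    doc = _doc_with([("mouse", "Species"), ("tp53", "Gene")])
    _, decisions = link_document(doc, {"Gene": kb_gene, "Species": kb_species})
    gene_decision = [d for d in decisions if d.mention.entity_type == "Gene"][0]
    assert gene_decision.code == "200"


def test_chemical_and_disease_descriptor_filters():
    kb_chem = KnowledgeBase("Chemical", [KBEntry("D001", "aspirin"), KBEntry("X001", "aspirin")])
    kb_dis = KnowledgeBase(
        "Disease",
        [KBEntry("C001", "glioma"), KBEntry("D999", "glioma"), KBEntry("OMIM:137800", "glioma")],
    )
    doc = _doc_with([("aspirin", "Chemical"), ("glioma", "Disease")])
    _, decisions = link_document(doc, {"Chemical": kb_chem, "Disease": kb_dis})
    assert decisions[0].code == "D001"  # non-descriptor chemical code filtered out
    assert decisions[1].candidates == frozenset() and decisions[1].code in {"C001", "OMIM:137800"}


def test_missing_kb_raises_configuration_error():
    doc = _doc_with([("aspirin", "Chemical")])
    with pytest.raises(LinkerConfigError):
        link_document(doc, {})
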