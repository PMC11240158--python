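"""Candidate pairs, marker insertion, the masked joint loss and sampling."""

import numpy as np
import pytest

from birex.documents import Document, EntityMention
from birex.encoding import MARKER_IDS, MARKER_S1, tokenize
from birex.extractor import (
    DEFAULT_TYPE_PAIRS,
    NEGATIVE_CLASS,
    CandidatePair,
    EntityGroup,
    ExtractorConfig,
    ExtractorModel,
    MarkingError,
    generate_pairs,
    group_entities,
    insert_markers,
    joint_loss,
    label_pairs,
    sample_negatives_dynamic,
    sample_negatives_random,
)
from birex.fixtures import ToyEncoder


def _doc(text, mentions):
    doc = Document("x", "t", text[2:]) if text.startswith("t ") else Document("x", "t", text)
    doc.mentions.extend(mentions)
    return doc


def _m(start, end, surface, etype, code):
    return EntityMention(start, end, surface, etype, frozenset([code]))


def test_group_entities_merges_mentions_by_code():
    doc = Document("g", "t", "BRCA1 and BRCA1 again")
    doc.mentions.append(_m(2, 7, "BRCA1", "Gene", "672"))
    doc.mentions.append(_m(12, 17, "BRCA1", "Gene", "672"))
    doc.mentions.append(EntityMention(18, 23, "again", "Disease"))  # unresolved
    groups = group_entities(doc)
    assert len(groups) == 1
    assert len(groups[0].mentions) == 2


def test_pair_generation_counts_and_type_filter():
    def grp(code, etype):
        return EntityGroup(code, etype, (EntityMention(0, 1, "x", etype, frozenset([code])),))

    groups = [grp("A", "Gene"), grp("B", "Disease"), grp("C", "Chemical")]
    assert len(generate_pairs(groups, None)) == 3  # C(3,2)
    with_species = groups + [grp("S", "Species")]
    pairs = generate_pairs(with_species, DEFAULT_TYPE_PAIRS)
    types = {frozenset((p.groups[0].entity_type, p.groups[1].entity_type)) for p in pairs}
    assert frozenset(("Species", "Gene")) not in types


def test_pair_canonical_order_is_construction_invariant():
    a = EntityGroup("zzz", "Gene", (EntityMention(0, 1, "x", "Gene", frozenset(["zzz"])),))
    b = EntityGroup("aaa", "Disease", (EntityMention(2, 3, "y", "Disease", frozenset(["aaa"])),))
    assert CandidatePair((a, b)).key == CandidatePair((b, a)).key == ("aaa", "zzz")


def test_negative_pair_cannot_carry_novelty():
    a = EntityGroup("a", "Gene", (EntityMention(0, 1, "x", "Gene", frozenset(["a"])),))
    b = EntityGroup("b", "Disease", (EntityMention(2, 3, "y", "Disease", frozenset(["b"])),))
    with pytest.raises(ValueError):
        CandidatePair((a, b), relation_label=NEGATIVE_CLASS, novelty_label=1)


def _glioma_doc():
    doc = Document("m", "t", "high-grade glioma involves BRCA1 here")
    doc.mentions.append(_m(13, 19, "glioma", "Disease", "C01"))
    doc.mentions.append(_m(29, 34, "BRCA1", "Gene", "672"))
    return doc


def test_markers_wrap_each_groups_mentions():
    doc = _glioma_doc()
    (pair,) = generate_pairs(group_entities(doc), None)
    marked = insert_markers(doc, pair)
    ids = list(marked.token_ids)
    tdoc = tokenize(doc.text)
    # two wrapped mentions add four marker tokens
    assert len(ids) == len(tdoc) + 4
    assert sorted(marked.marker_positions.tolist()) == sorted(
        i for i, t in enumerate(ids) if t in MARKER_IDS
    )
    # canonical order is lexicographic on identifiers: "672" < "C01", so the
    # s1 markers wrap the BRCA1 group
    s1 = ids.index(MARKER_S1)
    assert tdoc.token_ids[0] not in MARKER_IDS
    assert ids[s1 + 1] == tokenize("BRCA1").token_ids[0]


def test_marker_count_scales_with_group_mentions():
    doc = Document("m2", "t", "aa glioma bb glioma cc BRCA1 dd")
    doc.mentions.append(_m(5, 11, "glioma", "Disease", "C01"))
    doc.mentions.append(_m(15, 21, "glioma", "Disease", "C01"))
    doc.mentions.append(_m(25, 30, "BRCA1", "Gene", "672"))
    (pair,) = generate_pairs(group_entities(doc), None)
    marked = insert_markers(doc, pair)
    n1 = len(pair.groups[0].mentions)
    n2 = len(pair.groups[1].mentions)
    assert len(marked.marker_positions) == 2 * n1 + 2 * n2


def test_shared_mention_span_across_groups_rejected():
    doc = Document("m3", "t", "glioma")
    doc.mentions.append(_m(2, 8, "glioma", "Disease", "C01"))
    doc.mentions.append(_m(2, 8, "glioma", "Disease", "C02"))
    (pair,) = generate_pairs(group_entities(doc), None)
    with pytest.raises(MarkingError):
        insert_markers(doc, pair)


def test_truncation_keeps_marker_densest_window():
    long_tail = " ".join(["filler"] * 600)
    doc = Document("m4", "t", f"glioma BRCA1 {long_tail}")
    doc.mentions.append(_m(2, 8, "glioma", "Disease", "C01"))
    doc.mentions.append(_m(9, 14, "BRCA1", "Gene", "672"))
    (pair,) = generate_pairs(group_entities(doc), None)
    marked = insert_markers(doc, pair, max_tokens=64)
    assert len(marked.token_ids) == 64
    assert len(marked.marker_positions) == 4  # all markers retained


def test_joint_loss_masking_identity_and_limits():
    rel = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2])
    nov = np.array([0.3, 0.7])
    # negative class: exactly the relation term, novelty ignored
    assert joint_loss(rel, nov, NEGATIVE_CLASS, None) == pytest.approx(-np.log(0.2))
    # valid pair: both cross-entropies
    assert joint_loss(rel, nov, 2, 1) == pytest.approx(-np.log(0.1) - np.log(0.7))
    one_hot_r = np.eye(9)[3]
    one_hot_n = np.eye(2)[0]
    assert joint_loss(one_hot_r, one_hot_n, 3, 0) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        joint_loss(rel, nov, 2, None)


def test_novelty_head_gradient_exactly_zero_for_negative_pairs():
    doc = _glioma_doc()
    (pair,) = generate_pairs(group_entities(doc), None)
    encoder = ToyEncoder()
    model = ExtractorModel(encoder, ExtractorConfig(), np.random.default_rng(0))
    marked = insert_markers(doc, pair)
    _, (gQ, gW_r, gb_r, gW_n, gb_n) = model._step_grads(marked, NEGATIVE_CLASS, None)
    assert np.all(gW_n == 0.0) and np.all(gb_n == 0.0)
    assert np.any(gW_r != 0.0)
    # and a positive label does reach the novelty head
    _, (_, _, _, gW_n2, _) = model._step_grads(marked, 2, 1)
    assert np.any(gW_n2 != 0.0)


def test_forward_distributions_sum_to_one_and_are_deterministic():
    doc = _glioma_doc()
    (pair,) = generate_pairs(group_entities(doc), None)
    model = ExtractorModel(ToyEncoder(), ExtractorConfig(), np.random.default_rng(1))
    marked = insert_markers(doc, pair)
    p1 = model.forward(marked)
    p2 = model.forward(marked)
    assert p1.relation_scores.sum() == pytest.approx(1.0)
    assert p1.novelty_scores.sum() == pytest.approx(1.0)
    assert np.array_equal(p1.relation_scores, p2.relation_scores)


def _labelled_pairs(n_pos, n_neg):
    pairs = []
    for i in range(n_pos + n_neg):
        a = EntityGroup(f"a{i}", "Gene", (EntityMention(0, 1, "x", "Gene", frozenset([f"a{i}"])),))
        b = EntityGroup(f"b{i}", "Disease", (EntityMention(2, 3, "y", "Disease", frozenset([f"b{i}"])),))
        p = CandidatePair((a, b))
        if i < n_pos:
            p.relation_label, p.novelty_label = 0, 1
        else:
            p.relation_label = NEGATIVE_CLASS
        pairs.append(p)
    return pairs


def test_random_negative_sampling_arithmetic_and_determinism():
    pairs = _labelled_pairs(10, 100)
    rng = np.random.default_rng(5)
    sample = sample_negatives_random(pairs, 3.0, rng)
    assert sum(p.relation_label != NEGATIVE_CLASS for p in sample) == 10
    assert sum(p.relation_label == NEGATIVE_CLASS for p in sample) == 30
    few = sample_negatives_random(_labelled_pairs(10, 5), 3.0, np.random.default_rng(5))
    assert sum(p.relation_label == NEGATIVE_CLASS for p in few) == 5
    again = sample_negatives_random(pairs, 3.0, np.random.default_rng(5))
    assert [p.key for p in again] == [p.key for p in sample]


class _FixedModel:
    """Stand-in M0 emitting a fixed per-pair negative-class confidence."""

    def __init__(self, scores):
        self.scores = scores
        self.config = ExtractorConfig()
        self.calls = 0

    def forward(self, marked):
        from birex.extractor import JointPrediction

        p_neg, argmax_is_neg = self.scores[self.calls]
        self.calls += 1
        rel = np.full(9, (1 - p_neg) / 8)
        rel[NEGATIVE_CLASS] = p_neg
        if not argmax_is_neg:
            rel[3], rel[NEGATIVE_CLASS] = rel[NEGATIVE_CLASS], rel[3]
        return JointPrediction(rel, np.array([0.5, 0.5]))


def test_dynamic_sampling_keeps_hard_negatives_only():
    doc = _glioma_doc()
    pairs = generate_pairs(group_entities(doc), None) * 3
    for p in pairs:
        p.relation_label = NEGATIVE_CLASS
    # confident-negative, low-confidence, misclassified-as-positive
    m0 = _FixedModel([(0.99, True), (0.5, True), (0.99, False)])
    kept = sample_negatives_dynamic(pairs, m0, 0.9, dict(enumerate([doc] * 3)))
    assert len(kept) == 2  # the confident correct negative is dropped


def test_dynamic_sampling_tau_monotonicity():
    doc = _glioma_doc()
    pairs = generate_pairs(group_entities(doc), None) * 5
    for p in pairs:
        p.relation_label = NEGATIVE_CLASS
    confidences = [0.3, 0.5, 0.7, 0.8, 0.95]
    sizes = []
    for tau in (1.01, 0.75, 0.4, 0.0):
        m0 = _FixedModel([(c, True) for c in confidences])
        kept = sample_negatives_dynamic(pairs, m0, tau, dict(enumerate([doc] * 5)))
        sizes.append(len(kept))
    assert sizes[0] == 5  # tau above 1 keeps everything
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[-1] == 0  # tau 0 keeps only misclassified negatives (none here)
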