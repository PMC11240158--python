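"""Masked-CRF correctness against an exhaustive enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from birex.tagger import (
    CrfParams,
    build_label_schema,
    build_transition_mask,
    crf_log_partition,
    crf_nll,
    crf_sequence_score,
    crf_viterbi,
)


def enumerate_scores(unary: np.ndarray, params: CrfParams):
    """Oracle: score every label sequence by direct summation."""
    N, L = unary.shape
    T = params.effective_transitions()
    start, end = params.start_scores(), params.end_scores()
    paths = list(itertools.product(range(L), repeat=N))
    scores = []
    for path in paths:
        s = start[path[0]] + unary[0, path[0]] + end[path[-1]]
        for i in range(1, N):
            s += T[path[i - 1], path[i]] + unary[i, path[i]]
        scores.append(s)
    return paths, np.array(scores)


def unmasked_params(L: int, rng=None, transitions=None) -> CrfParams:
    T = transitions if transitions is not None else rng.normal(size=(L, L))
    return CrfParams(T, np.ones((L, L), bool), np.ones(L, bool), np.ones(L, bool))


def test_single_token_uniform_partition_is_log_two():
    params = unmasked_params(2, transitions=np.zeros((2, 2)))
    assert crf_log_partition(np.zeros((1, 2)), params) == pytest.approx(math.log(2))


def test_uniform_two_by_two_nll_is_log_four():
    params = unmasked_params(2, transitions=np.zeros((2, 2)))
    assert crf_nll(np.zeros((2, 2)), [0, 1], params) == pytest.approx(math.log(4))


def test_empty_sequence_rejected():
    params = unmasked_params(2, transitions=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        crf_log_partition(np.zeros((0, 2)), params)


@pytest.mark.parametrize("trial", range(20))
def test_log_partition_matches_enumeration(trial):
    rng = np.random.default_rng(100 + trial)
    N, L = int(rng.integers(1, 7)), int(rng.integers(2, 6))
    params = unmasked_params(L, rng)
    unary = rng.normal(size=(N, L))
    _, scores = enumerate_scores(unary, params)
    assert crf_log_partition(unary, params) == pytest.approx(logsumexp(scores), abs=1e-8)


def test_nll_equals_minus_log_enumerated_probability():
    rng = np.random.default_rng(7)
    unary = rng.normal(size=(4, 3))
    params = unmasked_params(3, rng)
    paths, scores = enumerate_scores(unary, params)
    gold = [0, 2, 1, 1]
    p_gold = np.exp(scores[paths.index(tuple(gold))] - logsumexp(scores))
    assert crf_nll(unary, gold, params) == pytest.approx(-math.log(p_gold), abs=1e-8)
    assert crf_nll(unary, gold, params) >= 0


def test_total_probability_sums_to_one_under_masking():
    rng = np.random.default_rng(13)
    schema = build_label_schema(["Gene", "Disease"])
    mask, start, end = build_transition_mask(schema)
    params = CrfParams(rng.normal(size=mask.shape), mask, start, end)
    unary = rng.normal(size=(5, len(schema)))
    paths, scores = enumerate_scores(unary, params)
    log_z = crf_log_partition(unary, params)
    total = sum(math.exp(-crf_nll(unary, list(p), params)) for p in paths)
    assert total == pytest.approx(1.0, abs=1e-6)
    assert log_z == pytest.approx(logsumexp(scores), abs=1e-8)


def test_masking_one_transition_lowers_log_partition_by_enumerated_amount():
    rng = np.random.default_rng(21)
    L = 3
    unary = rng.normal(size=(4, L))
    open_params = unmasked_params(L, rng)
    masked = CrfParams(
        open_params.transitions,
        np.ones((L, L), bool),
        np.ones(L, bool),
        np.ones(L, bool),
    )
    masked.mask[0, 1] = False
    _, open_scores = enumerate_scores(unary, open_params)
    _, masked_scores = enumerate_scores(unary, masked)
    assert crf_log_partition(unary, masked) == pytest.approx(
        logsumexp(masked_scores), abs=1e-8
    )
    assert crf_log_partition(unary, masked) < logsumexp(open_scores)


@pytest.mark.parametrize("trial", range(20))
def test_viterbi_matches_exhaustive_argmax(trial):
    rng = np.random.default_rng(300 + trial)
    N, L = int(rng.integers(1, 7)), int(rng.integers(2, 6))
    params = unmasked_params(L, rng)
    unary = rng.normal(size=(N, L))
    paths, scores = enumerate_scores(unary, params)
    best = paths[int(np.argmax(scores))]
    vit = crf_viterbi(unary, params)
    assert crf_sequence_score(unary, vit, params) == pytest.approx(
        float(np.max(scores)), abs=1e-8
    )
    assert tuple(vit) == best  # unique optimum with continuous scores


def test_viterbi_per_position_argmax_without_transitions():
    unary = np.array([[5.0, 0, 0], [0, 7.0, 0], [0, 0, 3.0]])
    params = unmasked_params(3, transitions=np.zeros((3, 3)))
    assert list(crf_viterbi(unary, params)) == [0, 1, 2]


def test_masked_viterbi_avoids_forbidden_path_and_stays_bio_valid():
    schema = build_label_schema(["Gene"])
    mask, start, end = build_transition_mask(schema)
    O, ig = schema.index["O"], schema.i("Gene")
    unary = np.zeros((2, 3))
    unary[0, O] = 5.0
    unary[1, ig] = 5.0  # unmasked argmax would be [O, I-Gene]
    open_params = unmasked_params(3, transitions=np.zeros((3, 3)))
    assert list(crf_viterbi(unary, open_params)) == [O, ig]
    masked = CrfParams(np.zeros((3, 3)), mask, start, end)
    path = crf_viterbi(unary, masked)
    assert list(path) != [O, ig]
    for a, b in zip(path, path[1:]):
        assert mask[a, b]


def test_gold_containing_masked_transition_warns_not_raises():
    schema = build_label_schema(["Gene"])
    mask, start, end = build_transition_mask(schema)
    params = CrfParams(np.zeros((3, 3)), mask, start, end)
    with pytest.warns(UserWarning):
        loss = crf_nll(np.zeros((2, 3)), [schema.index["O"], schema.i("Gene")], params)
    assert loss > 1000  # dominated by the mask weight


def test_unary_overwhelmingly_favoring_gold_drives_loss_to_zero():
    gold = [0, 1, 0]
    unary = np.full((3, 2), -50.0)
    for i, g in enumerate(gold):
        unary[i, g] = 50.0
    params = unmasked_params(2, transitions=np.zeros((2, 2)))
    assert crf_nll(unary, gold, params) == pytest.approx(0.0, abs=1e-6)
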