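"""Masked linear-chain CRF: log-partition, NLL, marginals and Viterbi.

The model scores a label sequence ``y`` for tokens ``x`` as the sum of unary
potentials (one score per token and label, produced by an affine map over
the encoder representation) and pairwise transition potentials looked up in
an ``L x L`` matrix, normalised by the partition function ``Z(x)``.
Transitions that violate the BIO schema are "masked" by adding a large
negative weight rather than negative infinity, which keeps all arithmetic
finite while making invalid paths astronomically improbable.

All recursions run in log space with log-sum-exp for stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

NEG_WEIGHT = -10_000.0


@dataclass
class CrfParams:
    """Transition scores, BIO mask and boundary constraints.

    ``transitions[i, j]`` scores label ``i`` followed by label ``j``; masked
    entries contribute ``transitions + neg_weight``.
    """

    transitions: np.ndarray  # (L, L) float
    mask: np.ndarray  # (L, L) bool, True = allowed
    start_allowed: np.ndarray  # (L,) bool
    end_allowed: np.ndarray  # (L,) bool
    neg_weight: float = NEG_WEIGHT

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)

    @property
    def n_labels(self) -> int:
        return self.transitions.shape[0]

    def effective_transitions(self) -> np.ndarray:
        return self.transitions + np.where(self.mask, 0.0, self.neg_weight)

    def start_scores(self) -> np.ndarray:
        return np.where(self.start_allowed, 0.0, self.neg_weight)

    def end_scores(self) -> np.ndarray:
        return np.where(self.end_allowed, 0.0, self.neg_weight)


def _check_unary(unary: np.ndarray, params: CrfParams) -> np.ndarray:
    unary = np.asarray(unary, dtype=float)
    if unary.ndim != 2 or unary.shape[0] < 1:
        raise ValueError("unary scores must be a non-empty N x L matrix")
    if unary.shape[1] != params.n_labels:
        raise ValueError("unary label dimension does not match transition matrix")
    return unary


def crf_log_partition(unary: np.ndarray, params: CrfParams) -> float:
    """log Z(x): log-sum-exp of path scores over all label sequences."""
    unary = _check_unary(unary, params)
    T = params.effective_transitions()
    alpha = params.start_scores() + unary[0]
    for i in range(1, unary.shape[0]):
        alpha = logsumexp(alpha[:, None] + T, axis=0) + unary[i]
    return float(logsumexp(alpha + params.end_scores()))


def crf_sequence_score(unary: np.ndarray, labels: np.ndarray, params: CrfParams) -> float:
    """Unnormalised path score of one label sequence (mask included)."""
    unary = _check_unary(unary, params)
    labels = np.asarray(labels, dtype=int)
    T = params.effective_transitions()
    score = params.start_scores()[labels[0]] + unary[0, labels[0]]
    for i in range(1, len(labels)):
        score += T[labels[i - 1], labels[i]] + unary[i, labels[i]]
    score += params.end_scores()[labels[-1]]
    return float(score)


def crf_nll(unary: np.ndarray, labels: np.ndarray, params: CrfParams) -> float:
    """Negative log-likelihood ``-log P(y | x) = log Z - score(y)``; >= 0."""
    labels = np.asarray(labels, dtype=int)
    T = params.mask
    for i in range(1, len(labels)):
        if not T[labels[i - 1], labels[i]]:
            warnings.warn(
                "gold labels contain a masked transition "
                f"{labels[i - 1]} -> {labels[i]}; loss dominated by the mask weight",
                stacklevel=2,
            )
            break
    return crf_log_partition(unary, params) - crf_sequence_score(unary, labels, params)


def crf_marginals(
    unary: np.ndarray, params: CrfParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward: per-position and pairwise posterior marginals.

    Returns ``(node_marginals (N, L), pair_marginals (N-1, L, L), log Z)``.
    Pair marginals are the expected transition counts used in the NLL
    gradient with respect to the transition matrix.
    """
    unary = _check_unary(unary, params)
    N, L = unary.shape
    T = params.effective_transitions()
    alpha = np.empty((N, L))
    beta = np.empty((N, L))
    alpha[0] = params.start_scores() + unary[0]
    for i in range(1, N):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + T, axis=0) + unary[i]
    beta[N - 1] = params.end_scores()
    for i in range(N - 2, -1, -1):
        beta[i] = logsumexp(T + unary[i + 1] + beta[i + 1], axis=1)
    log_z = float(logsumexp(alpha[N - 1] + beta[N - 1]))
    node = np.exp(alpha + beta - log_z)
    pair = np.empty((max(N - 1, 0), L, L))
    for i in range(N - 1):
        pair[i] = np.exp(
            alpha[i][:, None] + T + unary[i + 1] + beta[i + 1] - log_z
        )
    return node, pair, log_z


def crf_viterbi(unary: np.ndarray, params: CrfParams) -> np.ndarray:
    """Highest-scoring label sequence under the masked potentials.

    Ties break toward the lowest label index (first argmax), which never
    emits a masked transition as long as any unmasked path exists.
    """
    unary = _check_unary(unary, params)
    N, L = unary.shape
    T = params.effective_transitions()
    delta = params.start_scores() + unary[0]
    back = np.empty((N, L), dtype=int)
    for i in range(1, N):
        scores = delta[:, None] + T  # (from, to)
        back[i] = np.argmax(scores, axis=0)
        delta = scores[back[i], np.arange(L)] + unary[i]
    delta = delta + params.end_scores()
    path = np.empty(N, dtype=int)
    path[N - 1] = int(np.argmax(delta))
    for i in range(N - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path
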