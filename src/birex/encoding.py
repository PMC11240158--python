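"""Tokenization and the pluggable token-encoder contract.

The tagger and extractor are encoder-agnostic: anything satisfying
:class:`TokenEncoder` (a deterministic map from token-id sequences to an
``N x d`` representation matrix) can sit under them.  The package ships a
deterministic hash-based toy encoder (:mod:`birex.fixtures`) used throughout
the tests; a contextual transformer encoder can be plugged in through the
same contract.

Token ids are stable content hashes of the lowercased token string, so no
vocabulary object needs to be carried around; ids 0-7 are reserved for
special tokens ([UNK] and the four entity-marker tokens).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

UNK_ID = 0
MARKER_S1, MARKER_E1, MARKER_S2, MARKER_E2 = 1, 2, 3, 4
MARKER_IDS = (MARKER_S1, MARKER_E1, MARKER_S2, MARKER_E2)
MARKER_STRINGS = {MARKER_S1: "[s1]", MARKER_E1: "[e1]", MARKER_S2: "[s2]", MARKER_E2: "[e2]"}
_N_RESERVED = 8

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def token_to_id(token: str) -> int:
    """Stable 31-bit content hash; lowercased so ids are case-insensitive."""
    digest = hashlib.blake2b(token.lower().encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - _N_RESERVED) + _N_RESERVED


@dataclass
class TokenizedDoc:
    """Token ids plus per-token character spans into the source text."""

    token_ids: np.ndarray  # (N,) int64
    char_spans: list[tuple[int, int]]  # per-token [start, end)
    word_starts: np.ndarray  # (N,) bool; first sub-token of each word

    def __len__(self) -> int:
        return len(self.token_ids)


def tokenize(text: str) -> TokenizedDoc:
    """Split into word/punctuation tokens with exact character spans.

    This tokenizer is word-level (every token is a word start); a sub-word
    tokenizer can replace it as long as it reports ``char_spans`` and
    ``word_starts``.
    """
    ids, spans = [], []
    for m in _TOKEN_RE.finditer(text):
        ids.append(token_to_id(m.group()))
        spans.append((m.start(), m.end()))
    n = len(ids)
    return TokenizedDoc(
        token_ids=np.asarray(ids, dtype=np.int64),
        char_spans=spans,
        word_starts=np.ones(n, dtype=bool),
    )


class TokenEncoder(Protocol):
    """Deterministic map from token ids to an ``N x d`` representation matrix."""

    @property
    def dimension(self) -> int: ...

    def encode(self, token_ids: Sequence[int] | np.ndarray) -> np.ndarray: ...
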