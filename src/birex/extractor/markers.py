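"""Entity-marker insertion: wrap the candidate pair's mentions in reserved tokens.

The four marker tokens [s1]/[e1]/[s2]/[e2] delimit every mention of the
first and second entity group directly in the token sequence — e.g.
"... high-grade [s1]glioma[e1] ..." — so the encoder can expose
entity-aware positions for pooling.  Insertions are applied right-to-left
so earlier positions are not shifted by later insertions.  Inputs longer
than the encoder budget are truncated to the contiguous window containing
the most marker tokens (markers carry the pair signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..documents import Document
from ..encoding import MARKER_E1, MARKER_E2, MARKER_S1, MARKER_S2, TokenizedDoc, tokenize
from .pairs import CandidatePair


class MarkingError(ValueError):
    pass


@dataclass
class MarkedInput:
    """Token ids with markers inserted, plus the marker positions by role."""

    token_ids: np.ndarray
    s1_positions: np.ndarray  # positions of [s1] and [e1] tokens
    s2_positions: np.ndarray  # positions of [s2] and [e2] tokens

    @property
    def marker_positions(self) -> np.ndarray:
        return np.sort(np.concatenate([self.s1_positions, self.s2_positions]))


def _token_range(tdoc: TokenizedDoc, start: int, end: int) -> tuple[int, int]:
    """Token index range [a, b) of tokens intersecting character span [start, end)."""
    a = b = None
    for i, (s, e) in enumerate(tdoc.char_spans):
        if s < end and start < e:
            if a is None:
                a = i
            b = i + 1
    if a is None:
        raise MarkingError(f"mention span [{start}, {end}) covers no tokens")
    return a, b


def insert_markers(
    doc: Document, pair: CandidatePair, max_tokens: int | None = None
) -> MarkedInput:
    """Wrap group-1 mentions in [s1]..[e1] and group-2 mentions in [s2]..[e2]."""
    tdoc = tokenize(doc.text)
    g1, g2 = pair.groups
    spans: list[tuple[int, int, int, int]] = []  # (tok_start, tok_end, s_id, e_id)
    for group, s_id, e_id in ((g1, MARKER_S1, MARKER_E1), (g2, MARKER_S2, MARKER_E2)):
        for m in group.mentions:
            a, b = _token_range(tdoc, m.start, m.end)
            spans.append((a, b, s_id, e_id))
    spans.sort()
    for (a1, b1, *_), (a2, b2, *_) in zip(spans, spans[1:]):
        if a2 < b1:
            if (a1, b1) == (a2, b2):
                raise MarkingError(
                    f"{doc.doc_id}: the two groups share a mention span [{a1}, {b1})"
                )
            raise MarkingError(f"{doc.doc_id}: overlapping mentions across the pair")

    ids = list(map(int, tdoc.token_ids))
    roles: list[int] = [0] * len(ids)  # 0 text, 1 group1 marker, 2 group2 marker
    for a, b, s_id, e_id in reversed(spans):
        role = 1 if s_id == MARKER_S1 else 2
        ids.insert(b, e_id)
        roles.insert(b, role)
        ids.insert(a, s_id)
        roles.insert(a, role)

    ids_arr = np.asarray(ids, dtype=np.int64)
    roles_arr = np.asarray(roles)
    if max_tokens is not None and len(ids_arr) > max_tokens:
        is_marker = roles_arr > 0
        counts = np.convolve(is_marker.astype(int), np.ones(max_tokens, dtype=int), "valid")
        off = int(np.argmax(counts))
        ids_arr = ids_arr[off : off + max_tokens]
        roles_arr = roles_arr[off : off + max_tokens]
    return MarkedInput(
        token_ids=ids_arr,
        s1_positions=np.flatnonzero(roles_arr == 1),
        s2_positions=np.flatnonzero(roles_arr == 2),
    )
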