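"""BIO label encoding/decoding between character-offset mentions and token labels.

Labels are assigned at token granularity: every token whose character span
intersects a mention receives that mention's type, with ``B-`` on the first
such token and ``I-`` on the rest.  Decoding is total: an ``I`` following
``O`` or an ``I`` of a different type than its predecessor opens a new
mention (repair rule) — masked Viterbi never produces such sequences, but
the decoder must accept arbitrary label input.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..documents import EntityMention
from ..encoding import TokenizedDoc
from .schema import LabelSchema


class EncodingError(ValueError):
    pass


def encode_bio(
    tdoc: TokenizedDoc, mentions: Sequence[EntityMention], schema: LabelSchema
) -> np.ndarray:
    """Token-level BIO label indices for a set of non-overlapping mentions."""
    n = len(tdoc)
    labels = np.zeros(n, dtype=int)  # O
    owner: list[EntityMention | None] = [None] * n
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        first = True
        for i, (s, e) in enumerate(tdoc.char_spans):
            if s < m.end and m.start < e:  # span intersects mention
                if owner[i] is not None:
                    raise EncodingError(
                        f"mentions overlap at token {i}: {owner[i]!r} vs {m!r}"
                    )
                owner[i] = m
                labels[i] = schema.b(m.entity_type) if first else schema.i(m.entity_type)
                first = False
    return labels


def decode_bio(
    labels: Sequence[int], tdoc: TokenizedDoc, schema: LabelSchema, text: str
) -> list[EntityMention]:
    """Character-offset mentions from a token label sequence (never raises)."""
    mentions: list[EntityMention] = []
    cur_type: str | None = None
    cur_start = cur_end = 0

    def flush() -> None:
        nonlocal cur_type
        if cur_type is not None:
            mentions.append(
                EntityMention(cur_start, cur_end, text[cur_start:cur_end], cur_type)
            )
            cur_type = None

    for i, lab in enumerate(labels):
        etype = schema.entity_type_of(int(lab))
        span = tdoc.char_spans[i]
        if etype is None:
            flush()
        elif schema.is_begin(int(lab)) or etype != cur_type:
            # fresh entity, or orphan-I repair (treated as a new start)
            flush()
            cur_type, cur_start, cur_end = etype, span[0], span[1]
        else:
            cur_end = span[1]
    flush()
    return mentions
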