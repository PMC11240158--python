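"""BIO label schema and the valid-transition mask.

For k entity types the label space is ``[O, B-t1, I-t1, ..., B-tk, I-tk]``,
i.e. ``2k + 1`` labels — 13 for the six biomedical entity classes handled
here.  The transition mask encodes the BIO constraints that the masked CRF
enforces with a large negative weight: an ``I-t`` may only follow ``B-t`` or
``I-t`` of the same type, and no sequence may start inside an entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..documents import ENTITY_TYPES

O_LABEL = "O"


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class LabelSchema:
    entity_types: tuple[str, ...]
    labels: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def label_of(self, i: int) -> str:
        return self.labels[i]

    def b(self, entity_type: str) -> int:
        return self.index[f"B-{entity_type}"]

    def i(self, entity_type: str) -> int:
        return self.index[f"I-{entity_type}"]

    def entity_type_of(self, label_index: int) -> str | None:
        """Entity type of a B-/I- label, None for O."""
        lab = self.labels[label_index]
        return None if lab == O_LABEL else lab[2:]

    def is_begin(self, label_index: int) -> bool:
        return self.labels[label_index].startswith("B-")

    def is_inside(self, label_index: int) -> bool:
        return self.labels[label_index].startswith("I-")


def build_label_schema(entity_types: Sequence[str] = ENTITY_TYPES) -> LabelSchema:
    """Build the ``[O, B-t, I-t, ...]`` label space for the given types."""
    types = tuple(entity_types)
    if len(set(types)) != len(types):
        raise SchemaError(f"duplicate entity type in {types}")
    if any(not t for t in types):
        raise SchemaError("empty entity type name")
    labels = [O_LABEL]
    for t in types:
        labels.extend((f"B-{t}", f"I-{t}"))
    return LabelSchema(entity_types=types, labels=tuple(labels))


def build_transition_mask(schema: LabelSchema) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (allowed) transition matrix plus start/end allowed vectors.

    Disallowed: ``O -> I-t``, ``B-s -> I-t`` and ``I-s -> I-t`` for ``s != t``,
    and starting a sequence at any ``I-t``.  Every other transition — and
    ending anywhere — is allowed.
    """
    L = len(schema)
    mask = np.ones((L, L), dtype=bool)
    start_allowed = np.ones(L, dtype=bool)
    end_allowed = np.ones(L, dtype=bool)
    for j in range(L):
        if not schema.is_inside(j):
            continue
        t = schema.entity_type_of(j)
        start_allowed[j] = False
        for i in range(L):
            # I-t reachable only from B-t / I-t of the same type
            mask[i, j] = schema.entity_type_of(i) == t and not schema.labels[i] == O_LABEL
    return mask, start_allowed, end_allowed
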