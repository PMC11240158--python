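"""Trainable masked-CRF tagger: augmentation, training loop, inference, ensembling.

The unary potential is an affine map from the (pluggable) encoder's token
representation to per-label scores; transition potentials are a trainable
``L x L`` matrix with the BIO mask applied as a large negative additive
weight.  Training minimises the mean CRF negative log-likelihood by
stochastic gradient steps (Adam) using exact forward-backward gradients:
``d NLL / d unary = marginals - onehot(gold)`` and
``d NLL / d transitions = E[pair counts] - observed pair counts``.

During training, entity tokens are randomly replaced by the unknown token
so the model also learns from context rather than entity surface alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ..documents import Document, EntityMention, sort_mentions
from ..encoding import UNK_ID, TokenEncoder, TokenizedDoc, tokenize
from .bio import decode_bio, encode_bio
from .crf import CrfParams, crf_marginals, crf_nll, crf_viterbi
from .schema import LabelSchema, build_label_schema, build_transition_mask
from .windows import make_windows


def augment_unk(
    token_ids: np.ndarray,
    entity_token_flags: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replace each entity-flagged token by [UNK] independently with ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    out = np.array(token_ids, copy=True)
    flags = np.asarray(entity_token_flags, dtype=bool)
    replace = flags & (rng.random(len(out)) < rate)
    out[replace] = UNK_ID
    return out


def ensemble_entities(
    runs: Sequence[Sequence[EntityMention]], min_votes: int | None = None
) -> list[EntityMention]:
    """Entity-level majority vote over the outputs of several models.

    A mention is kept iff the exact (start, end, type) triple appears in at
    least ``min_votes`` runs (default: ceil of half the runs).
    """
    if not runs:
        raise ValueError("ensemble requires at least one run")
    if min_votes is None:
        min_votes = -(-len(runs) // 2)
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    votes: dict[tuple[int, int, str], int] = {}
    rep: dict[tuple[int, int, str], EntityMention] = {}
    for run in runs:
        for m in {(m.start, m.end, m.entity_type): m for m in run}.values():
            key = (m.start, m.end, m.entity_type)
            votes[key] = votes.get(key, 0) + 1
            rep.setdefault(key, m)
    kept = [rep[k] for k, v in votes.items() if v >= min_votes]
    return sort_mentions(kept)


@dataclass
class TaggerConfig:
    window: int = 512
    k: int = 32
    unk_rate: float = 0.15
    epochs: int = 20
    lr: float = 0.05
    seed: int = 0


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr, self.t = lr, 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TaggerModel:
    """A trained tagger: encoder reference + affine unary map + CRF parameters."""

    schema: LabelSchema
    encoder: TokenEncoder
    weights: np.ndarray  # (d, L)
    bias: np.ndarray  # (L,)
    crf: CrfParams
    config: TaggerConfig

    def unary(self, reps: np.ndarray) -> np.ndarray:
        return reps @ self.weights + self.bias

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "entity_types": list(self.schema.entity_types),
            "config": asdict(self.config),
            "neg_weight": self.crf.neg_weight,
        }
        (directory / "tagger.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            directory / "tagger.npz",
            weights=self.weights,
            bias=self.bias,
            transitions=self.crf.transitions,
        )

    @classmethod
    def load(cls, directory: str | Path, encoder: TokenEncoder) -> "TaggerModel":
        directory = Path(directory)
        meta = json.loads((directory / "tagger.json").read_text())
        arrays = np.load(directory / "tagger.npz")
        schema = build_label_schema(meta["entity_types"])
        mask, start, end = build_transition_mask(schema)
        crf = CrfParams(arrays["transitions"], mask, start, end, meta["neg_weight"])
        return cls(
            schema=schema,
            encoder=encoder,
            weights=arrays["weights"],
            bias=arrays["bias"],
            crf=crf,
            config=TaggerConfig(**meta["config"]),
        )


def _doc_examples(doc: Document, schema: LabelSchema, config: TaggerConfig):
    """Per-window (token_ids, entity_flags, gold labels) triples for one document."""
    tdoc = tokenize(doc.text)
    if len(tdoc) == 0:
        return []
    gold = encode_bio(tdoc, doc.mentions, schema)
    entity_flags = gold != 0
    out = []
    for w in make_windows(len(tdoc), config.window, config.k):
        out.append(
            (
                tdoc.token_ids[w.start : w.end],
                entity_flags[w.start : w.end],
                gold[w.start : w.end],
            )
        )
    return out


def train_tagger(
    corpus: Sequence[Document],
    encoder: TokenEncoder,
    config: TaggerConfig | None = None,
    entity_types: Sequence[str] | None = None,
    return_loss_trace: bool = False,
):
    """Fit unary map + transitions by Adam on the masked-CRF NLL.

    Deterministic given ``config.seed`` and the encoder.  With
    ``return_loss_trace`` the per-epoch mean NLL is returned alongside the
    model.
    """
    config = config or TaggerConfig()
    schema = build_label_schema(entity_types or _types_in(corpus))
    if not any(doc.mentions for doc in corpus):
        warnings.warn("training corpus contains no entity mentions", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    L, d = len(schema), encoder.dimension
    mask, start_allowed, end_allowed = build_transition_mask(schema)
    W = rng.normal(0.0, 0.01, size=(d, L))
    b = np.zeros(L)
    T = np.zeros((L, L))
    crf = CrfParams(T, mask, start_allowed, end_allowed)
    opt = _Adam([W.shape, b.shape, T.shape], config.lr)

    examples = []
    for doc in corpus:
        examples.extend(_doc_examples(doc, schema, config))

    trace = []
    order = np.arange(len(examples))
    for _ in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for idx in order:
            ids, flags, gold = examples[idx]
            ids_aug = augment_unk(ids, flags, config.unk_rate, rng)
            reps = encoder.encode(ids_aug)
            unary = reps @ W + b
            node, pair, log_z = crf_marginals(unary, crf)
            gold_onehot = np.zeros_like(node)
            gold_onehot[np.arange(len(gold)), gold] = 1.0
            d_unary = node - gold_onehot
            epoch_loss += crf_nll(unary, gold, crf)
            gT = pair.sum(axis=0)
            for i in range(1, len(gold)):
                gT[gold[i - 1], gold[i]] -= 1.0
            opt.step([W, b, T], [reps.T @ d_unary, d_unary.sum(axis=0), gT])
        trace.append(epoch_loss / max(len(examples), 1))

    model = TaggerModel(schema, encoder, W, b, crf, config)
    return (model, trace) if return_loss_trace else model


def _types_in(corpus: Sequence[Document]) -> tuple[str, ...]:
    from ..documents import ENTITY_TYPES

    seen = {m.entity_type for doc in corpus for m in doc.mentions}
    return tuple(t for t in ENTITY_TYPES if t in seen) or ENTITY_TYPES


def tag_document(doc: Document, model: TaggerModel) -> list[EntityMention]:
    """Tokenize, window, Viterbi-decode and stitch mentions for one document."""
    tdoc = tokenize(doc.text)
    if len(tdoc) == 0:
        return []
    labels = np.zeros(len(tdoc), dtype=int)
    for w in make_windows(len(tdoc), model.config.window, model.config.k):
        reps = model.encoder.encode(tdoc.token_ids[w.start : w.end])
        path = crf_viterbi(model.unary(reps), model.crf)
        a, b_ = w.predict_start - w.start, w.predict_end - w.start
        labels[w.predict_start : w.predict_end] = path[a:b_]
    return decode_bio(labels, tdoc, model.schema, doc.text)
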