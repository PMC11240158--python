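"""Joint relation + novelty classifier over entity-marker representations.

The encoder produces contextual token representations; the rows at the
marker-token positions are pooled through a multi-head attention layer with
learned query vectors into one joint vector, from which two affine heads
predict (i) a 9-way relation distribution (eight relation types plus the
negative class) and (ii) a binary novelty distribution.  Attention heads
are role-restricted: half attend over the first entity's markers, half over
the second's, so the joint vector always sees both entities.

Training minimises the masked combined loss

    L = L_r + [y_r != 8] * L_n

i.e. the novelty cross-entropy contributes only for pairs that carry a
relation; for negative pairs the novelty head receives exactly zero
gradient.  Negatives vastly outnumber positives, so training samples them:
randomly at a fixed negatives-per-positive ratio, or dynamically by keeping
only the negatives a first-pass model M0 finds hard (low confidence in the
negative class, or misclassified as positive) to train the final model M1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ..documents import RELATION_TYPES, Document, RelationInstance
from ..encoding import TokenEncoder
from .markers import MarkedInput, insert_markers
from .pairs import (
    DEFAULT_TYPE_PAIRS,
    NEGATIVE_CLASS,
    N_RELATION_CLASSES,
    CandidatePair,
    generate_pairs,
    group_entities,
    label_pairs,
)


@dataclass
class JointPrediction:
    relation_scores: np.ndarray  # (9,) distribution
    novelty_scores: np.ndarray  # (2,) distribution

    def __post_init__(self) -> None:
        for p in (self.relation_scores, self.novelty_scores):
            if not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError("prediction scores must form a distribution")


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - np.max(x)
    e = np.exp(x)
    return e / e.sum()


def joint_loss(
    relation_scores: np.ndarray,
    novelty_scores: np.ndarray,
    y_r: int,
    y_n: int | None,
) -> float:
    """Masked combined cross-entropy over the two output distributions."""
    if not 0 <= y_r < N_RELATION_CLASSES:
        raise ValueError(f"relation label {y_r} out of range")
    if y_r != NEGATIVE_CLASS and y_n is None:
        raise ValueError("non-negative pair requires a novelty label")
    eps = 1e-12
    loss = -float(np.log(relation_scores[y_r] + eps))
    if y_r != NEGATIVE_CLASS:
        loss += -float(np.log(novelty_scores[y_n] + eps))
    return loss


@dataclass
class ExtractorConfig:
    n_heads: int = 4  # split evenly between the two entity roles
    max_tokens: int = 512
    epochs: int = 40
    lr: float = 0.02
    seed: int = 0
    negative_ratio: float = 3.0
    tau: float = 0.9  # dynamic-sampling confidence threshold
    allow_all_type_pairs: bool = False


class ExtractorModel:
    """Attention-pooling joint classifier; parameters trained by Adam."""

    def __init__(self, encoder: TokenEncoder, config: ExtractorConfig, rng: np.random.Generator):
        self.encoder = encoder
        self.config = config
        d = encoder.dimension
        H = config.n_heads
        if H % 2:
            raise ValueError("n_heads must be even (half per entity role)")
        self.query = rng.normal(0.0, 0.1, size=(H, d))
        # joint vector: concatenated head outputs plus the element-wise product
        # of the two role means, which exposes features shared by both entities
        joint_dim = H * d + d
        self.W_r = rng.normal(0.0, 0.01, size=(joint_dim, N_RELATION_CLASSES))
        self.b_r = np.zeros(N_RELATION_CLASSES)
        self.W_n = rng.normal(0.0, 0.01, size=(joint_dim, 2))
        self.b_n = np.zeros(2)

    # ---- forward / backward -------------------------------------------------

    def _pool(self, reps: np.ndarray, marked: MarkedInput):
        """Role-restricted multi-head attention pooling over marker positions."""
        d = self.encoder.dimension
        H = self.config.n_heads
        half = H // 2
        zs, caches = [], []
        for h in range(H):
            pos = marked.s1_positions if h < half else marked.s2_positions
            R = reps[pos]  # (m, d)
            s = R @ self.query[h] / np.sqrt(d)
            a = _softmax(s)
            zs.append(a @ R)
            caches.append((R, a))
        u = np.mean(zs[:half], axis=0)  # role-1 summary
        v = np.mean(zs[half:], axis=0)  # role-2 summary
        return np.concatenate(zs + [u * v]), (caches, u, v)

    def forward(self, marked: MarkedInput) -> JointPrediction:
        z, _ = self._forward_z(marked)
        return JointPrediction(
            relation_scores=_softmax(z @ self.W_r + self.b_r),
            novelty_scores=_softmax(z @ self.W_n + self.b_n),
        )

    def _forward_z(self, marked: MarkedInput):
        if len(marked.s1_positions) == 0 or len(marked.s2_positions) == 0:
            raise ValueError("marked input lacks marker tokens for one entity role")
        reps = self.encoder.encode(marked.token_ids)
        return self._pool(reps, marked)

    def _step_grads(self, marked: MarkedInput, y_r: int, y_n: int | None):
        d = self.encoder.dimension
        H = self.config.n_heads
        half = H // 2
        z, (caches, u, v) = self._forward_z(marked)
        p_r = _softmax(z @ self.W_r + self.b_r)
        p_n = _softmax(z @ self.W_n + self.b_n)
        loss = joint_loss(p_r, p_n, y_r, y_n)

        d_lr = p_r.copy()
        d_lr[y_r] -= 1.0
        gW_r = np.outer(z, d_lr)
        gb_r = d_lr
        dz = self.W_r @ d_lr
        if y_r != NEGATIVE_CLASS:
            d_ln = p_n.copy()
            d_ln[y_n] -= 1.0
            gW_n = np.outer(z, d_ln)
            gb_n = d_ln
            dz = dz + self.W_n @ d_ln
        else:
            # masked loss: the novelty head gets exactly zero gradient
            gW_n = np.zeros_like(self.W_n)
            gb_n = np.zeros_like(self.b_n)

        d_int = dz[H * d :]  # gradient into the u*v interaction channel
        du, dv = d_int * v, d_int * u
        gQ = np.zeros_like(self.query)
        for h in range(H):
            R, a = caches[h]
            dz_h = dz[h * d : (h + 1) * d] + (du if h < half else dv) / half
            da = R @ dz_h
            ds = a * (da - float(a @ da))
            gQ[h] = R.T @ ds / np.sqrt(d)
        return loss, (gQ, gW_r, gb_r, gW_n, gb_n)

    # ---- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "extractor.json").write_text(json.dumps(asdict(self.config), indent=2))
        np.savez(
            directory / "extractor.npz",
            query=self.query, W_r=self.W_r, b_r=self.b_r, W_n=self.W_n, b_n=self.b_n,
        )

    @classmethod
    def load(cls, directory: str | Path, encoder: TokenEncoder) -> "ExtractorModel":
        directory = Path(directory)
        config = ExtractorConfig(**json.loads((directory / "extractor.json").read_text()))
        model = cls(encoder, config, np.random.default_rng(0))
        arrays = np.load(directory / "extractor.npz")
        model.query = arrays["query"]
        model.W_r, model.b_r = arrays["W_r"], arrays["b_r"]
        model.W_n, model.b_n = arrays["W_n"], arrays["b_n"]
        return model


# ---- negative sampling ------------------------------------------------------


def sample_negatives_random(
    pairs: Sequence[CandidatePair], ratio: float, rng: np.random.Generator
) -> list[CandidatePair]:
    """All positives plus ceil(ratio * positives) negatives without replacement."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    positives = [p for p in pairs if p.relation_label != NEGATIVE_CLASS]
    negatives = [p for p in pairs if p.relation_label == NEGATIVE_CLASS]
    want = min(len(negatives), int(np.ceil(ratio * len(positives))))
    chosen = list(rng.choice(len(negatives), size=want, replace=False)) if want else []
    return positives + [negatives[i] for i in chosen]


def sample_negatives_dynamic(
    pairs: Sequence[CandidatePair],
    model_m0: "ExtractorModel",
    tau: float,
    docs_by_pair: dict[int, Document],
) -> list[CandidatePair]:
    """Positives plus the negatives M0 finds hard.

    A negative is kept when M0's confidence in the negative class falls
    below ``tau`` or M0 misclassifies it as a positive class.
    """
    kept = []
    for i, p in enumerate(pairs):
        if p.relation_label != NEGATIVE_CLASS:
            kept.append(p)
            continue
        marked = insert_markers(docs_by_pair[i], p, model_m0.config.max_tokens)
        pred = model_m0.forward(marked)
        p_neg = float(pred.relation_scores[NEGATIVE_CLASS])
        if p_neg < tau or int(np.argmax(pred.relation_scores)) != NEGATIVE_CLASS:
            kept.append(p)
    return kept


# ---- training / inference ---------------------------------------------------


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr, self.t = lr, 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / (1 - b1**self.t)) / (np.sqrt(v / (1 - b2**self.t)) + eps)


def _training_pairs(corpus: Sequence[Document], config: ExtractorConfig):
    allowed = None if config.allow_all_type_pairs else DEFAULT_TYPE_PAIRS
    pairs, docs = [], []
    for doc in corpus:
        doc_pairs = generate_pairs(group_entities(doc), allowed)
        label_pairs(doc, doc_pairs)
        pairs.extend(doc_pairs)
        docs.extend([doc] * len(doc_pairs))
    return pairs, docs


def _fit(
    pairs: Sequence[CandidatePair],
    docs: Sequence[Document],
    encoder: TokenEncoder,
    config: ExtractorConfig,
    rng: np.random.Generator,
) -> ExtractorModel:
    model = ExtractorModel(encoder, config, rng)
    marked = [insert_markers(doc, p, config.max_tokens) for p, doc in zip(pairs, docs)]
    params = [model.query, model.W_r, model.b_r, model.W_n, model.b_n]
    opt = _Adam(params, config.lr)
    order = np.arange(len(pairs))
    for _ in range(config.epochs):
        rng.shuffle(order)
        for i in order:
            p = pairs[i]
            _, grads = model._step_grads(marked[i], p.relation_label, p.novelty_label)
            opt.step(params, grads)
    return model


def train_extractor(
    corpus: Sequence[Document],
    encoder: TokenEncoder,
    sampling_strategy: Literal["random", "dynamic"] = "random",
    config: ExtractorConfig | None = None,
) -> ExtractorModel:
    """Train the joint classifier on linked documents with gold relations.

    ``dynamic`` first trains M0 on a random negative sample, re-scores all
    candidate negatives with it, and trains M1 on the hard ones only.
    """
    config = config or ExtractorConfig()
    rng = np.random.default_rng(config.seed)
    all_pairs, all_docs = _training_pairs(corpus, config)
    if not any(p.relation_label != NEGATIVE_CLASS for p in all_pairs):
        raise ValueError("training corpus contains no positive relation pairs")

    sampled = sample_negatives_random(all_pairs, config.negative_ratio, rng)
    index_of = {id(p): i for i, p in enumerate(all_pairs)}
    docs_for = lambda sel: [all_docs[index_of[id(p)]] for p in sel]  # noqa: E731
    m0 = _fit(sampled, docs_for(sampled), encoder, config, rng)
    if sampling_strategy == "random":
        return m0
    if sampling_strategy != "dynamic":
        raise ValueError(f"unknown sampling strategy {sampling_strategy!r}")
    hard = sample_negatives_dynamic(all_pairs, m0, config.tau, dict(enumerate(all_docs)))
    if not hard:
        warnings.warn("dynamic sampling kept no pairs; falling back to M0", stacklevel=2)
        return m0
    return _fit(hard, docs_for(hard), encoder, config, np.random.default_rng(config.seed + 1))


def predict_relations(doc: Document, model: ExtractorModel) -> list[RelationInstance]:
    """Argmax relation per candidate pair; negative-class pairs are omitted."""
    allowed = None if model.config.allow_all_type_pairs else DEFAULT_TYPE_PAIRS
    out = []
    for pair in generate_pairs(group_entities(doc), allowed):
        marked = insert_markers(doc, pair, model.config.max_tokens)
        pred = model.forward(marked)
        r = int(np.argmax(pred.relation_scores))
        if r == NEGATIVE_CLASS:
            continue
        novelty = bool(np.argmax(pred.novelty_scores))
        out.append(RelationInstance(pair.key, RELATION_TYPES[r], novelty))
    out.sort(key=lambda r: (r.pair, r.relation_type))
    return out
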