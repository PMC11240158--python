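"""Train the masked-CRF tagger on a synthetic corpus and tag unseen text.

The tagger is a linear-chain CRF over a pluggable token encoder; invalid
BIO transitions (I after O, type switches inside an entity) carry a large
negative weight, so Viterbi decoding can never produce them.
"""

from birex.documents import Document
from birex.evaluation import eval_ner
from birex.fixtures import FixtureConfig, ToyEncoder, make_toy_corpus
from birex.tagger import TaggerConfig, tag_document, train_tagger

docs = make_toy_corpus(FixtureConfig(n_docs=60, seed=42))
train, held = docs[:50], docs[50:]

model, trace = train_tagger(
    train, ToyEncoder(), TaggerConfig(epochs=6, seed=0), return_loss_trace=True
)
print(f"mean CRF negative log-likelihood: {trace[0]:.2f} (epoch 1) -> {trace[-1]:.2f} (final)")

doc = held[0]
for m in tag_document(doc, model):
    print(f"  [{m.start:>4},{m.end:>4}) {m.entity_type:<9} {doc.text[m.start:m.end]!r}")

pred = [Document(d.doc_id, d.title, d.abstract, mentions=tag_document(d, model)) for d in held]
report = eval_ner(held, pred)
print(f"held-out span micro-F1: {report.overall.f1:.3f}")
# F1 near 1.0: the planted corpus draws entity surfaces from disjoint
# per-type vocabularies, so spans and types are recoverable by design.
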