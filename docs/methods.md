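# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind the package, and what the synthetic test
corpus does and does not demonstrate.

## Document model and corpus dialect

A document is a title and abstract joined by a single space; all
character offsets are 0-based and end-exclusive over that joined text,
and every mention's surface must equal the text slice at its offsets
(enforced on read and write). Relations are undirected and live at the
level of knowledge-base identifiers; pairs are stored lexicographically
sorted, which makes direction-of-construction irrelevant everywhere
downstream. The PubTator reader is strict — every non-blank line must
parse as title, abstract, annotation or relation, with errors naming the
line — because silent line-dropping is the classic corpus-I/O failure
mode. Composite identifier fields split on `,` and `;`; unlinked
mentions serialize as `-`; novelty reads tolerantly ("Novel" → true,
anything else → false) and writes canonically ("Novel"/"No").

## Tagger

The tagger is a linear-chain CRF whose unary potentials are an affine
map from the token encoder's representation (dimension d) to the 2k+1
BIO labels, and whose transition potentials are a learned L×L matrix.
Invalid BIO transitions (O→I-t; B-s/I-s→I-t with s≠t; sequence start at
I-t) are masked by **adding −10 000** rather than −∞: the "large
negative weight" keeps all arithmetic finite (no NaN propagation through
log-sum-exp) while making invalid paths ~e^10000 times less likely than
any valid one, so masked Viterbi output never contains them in practice
(and the tests check this over 1000 random parameter draws).

All recursions (forward, backward, Viterbi) run in log space. Training
minimises the exact negative log-likelihood with Adam (default lr 0.05,
20 epochs) using the closed-form CRF gradients: node marginals minus the
gold one-hot for the unary map, and pairwise marginals minus observed
transition counts for the transition matrix. Viterbi ties break toward
the lowest label index for determinism.

Labels are assigned to every token of a mention (B- on the first, I- on
the rest); decoding is total — an I following O, or an I whose type
differs from its predecessor, opens a new mention — so arbitrary label
sequences decode without error even though the masked CRF cannot emit
them.

Sliding windows use stride = window − 2k (default 512 and k = 32), so
interior windows carry k context tokens on each side inside the window
budget and the kept prediction ranges partition the token indices
exactly once; edge windows truncate context at the document boundary.
The UNK augmentation rate defaults to 0.15 per entity token. Entity-level
ensembling keeps a (start, end, type) span iff it appears in at least
⌈runs/2⌉ outputs; both values are configurable.

## Linker

Stages run per mention in a fixed order and the first resolving stage is
final: training-dictionary exact match, knowledge-base exact match
(always on lowercased terms), embedding semantic search, document-level
disambiguation. The semantic threshold defaults to cosine 0.70
(per-type configurable). A stage that yields several candidate codes
defers to disambiguation, which counts, over the document, how often
each code occurs among resolved assignments and candidate sets, then
gives every ambiguous mention its best-supported candidate (ties to the
lexicographically smallest code). Counting support from the *original*
decision state makes the operation idempotent and order-independent.

Per-type rules: Species never use semantic search (exact matching
against a taxonomy is already near-exhaustive, and spurious semantic
hits on short names are costly); Chemical codes are filtered to MeSH "D"
descriptors and Disease codes to "C" descriptors plus OMIM; Gene lookups
are partitioned by organism, chosen as the linked code of the nearest
Species mention by character gap (ties to the earlier mention), with
human (9606) as the default when the document mentions no species.
Variants first consult an injected offline dbSNP-style lookup keyed by
(surface, nearest-gene code); on a miss they fall back to rule-based
tmVar code generation. The decision records which path resolved it
(`variant_lookup` / `tmvar_generated`).

tmVar generation infers the sequence-type prefix from cues — an explicit
`c./r./g./p./m.` prefix wins; protein-residue names imply `p`; bare
A/C/G/T alleles default to `c` — because the prefix is the dominant
failure mode of learned generators and the cues are reliable. Amino
acids (three-letter or full names) and codons normalize to single-letter
residue codes through the standard genetic code (stop codons → `*`). A
substitution with no target allele is always rewritten as an `Allele`
code (`c|SUB|C|1188|` → `c|Allele|C|1188`), per the notation guidelines.
The generator handles substitutions, deletions, insertions,
duplications, bare-allele forms and rs identifiers; anything else is an
explicit generation error that the cascade records as unresolved.

## Extractor

Entity groups collect all mentions sharing a (code, type); candidate
pairs are unordered pairs of distinct groups whose type combination is
one of the eight observed in the corpus (Disease–Gene, Chemical–Gene,
Disease–Variant, Gene–Gene, Chemical–Disease, Chemical–Chemical,
Chemical–Variant, Variant–Variant), configurable off. Markers wrap
*every* mention of each group — document-level relations need all
occurrences visible — inserted right-to-left so earlier offsets never
shift. Inputs over the encoder budget are truncated to the contiguous
window holding the most marker tokens, since the markers carry the pair
signal.

Pooling is multi-head attention with learned query vectors in which half
the heads attend over the first group's marker positions and half over
the second's (role-restricted heads guarantee both entities contribute
to the joint vector); the joint representation concatenates the head
outputs with the element-wise product of the two role means, which makes
features *shared* by both entities linearly readable by the heads. Two
affine softmax heads produce the 9-way relation and binary novelty
distributions. The combined loss adds the novelty cross-entropy only
when the gold relation is not the negative class (index 8); on negative
pairs the novelty head's gradient is exactly zero by construction, not
merely small.

Negative sampling: the random strategy keeps all positives plus
⌈3·positives⌉ negatives (seeded, without replacement); the dynamic
strategy trains M0 on a random sample, keeps only negatives where M0's
negative-class confidence falls below τ = 0.9 or that M0 misclassifies
as positive, and trains M1 on those (a single iteration). At the toy
scale used here dynamic sampling *hurts* held-out precision — M1 sees
almost no easy negatives and over-predicts positives — so the random
strategy is the default; the dynamic machinery is fully implemented and
structurally tested (kept set shrinks monotonically with τ, positives
always kept).

Training is Adam (lr 0.02, default 40 epochs) with exact manual
gradients through the heads, the interaction channel and the attention
softmax; the encoder itself is not trained.

## Evaluation

Micro-averaged precision/recall/F1 with counts pooled over documents.
Relations are matched within a document on the canonical identifier
pair, at four nested levels (pair; +type; +novelty; all); by
construction F1(all) ≤ min(F1(pair+relation), F1(pair+novelty)) ≤
F1(pair). NER matching is strict on (start, end, type). Linking
additionally requires the predicted and gold code sets to intersect
(not be equal), since gold annotations may carry composite identifiers.
All 0/0 ratios are 0.

## Synthetic corpus: what it shows and what it does not

The generator emulates the *structure* of an annotated corpus — six
entity types with per-mention codes, eight relation types with novelty
flags, offsets consistent with the text — while making labels
recoverable by design: entity surfaces come from disjoint per-type
vocabularies, and each planted relation is a dedicated sentence
`<relation-trigger> <mention of A> <novelty-trigger> <mention of B> .`
whose trigger tokens determine relation type and novelty. Defaults:
200 documents, 10 surfaces per type (a quarter two-token), relation
probability 0.45 per eligible co-occurring pair, novelty proportion 0.7
(matching the roughly 70 % novel share in real annotated corpora of this
kind), variant lookup covering about a third of variant surfaces, all
seeded. The toy encoder concatenates a 128-dimensional per-token hash
embedding with the mean of base vectors in a ±3-token window; with a
vocabulary of ~100 distinct tokens in 128 dimensions, token identity and
nearby triggers are linearly separable, which is what makes the recovery
runs (tagger span F1 ≥ 0.9; extractor pair F1 ≥ 0.8 and novelty
accuracy ≥ 0.85 on 40 held-out documents after training on 160) succeed.

Passing these tests therefore demonstrates that the machinery —
windowing, masked CRF training and decoding, cascade precedence, marker
insertion, the masked joint loss, the metrics — is correct, *not* that
the models reach any particular accuracy on real abstracts: the corpus
has none of the lexical ambiguity, discourse structure, annotation noise
or knowledge-base drift of real data, and relation-type accuracy on
documents where one entity participates in several relations is visibly
the hardest signal for the toy encoder (the pair and novelty levels
saturate first). Real-corpus performance requires a contextual
transformer encoder behind the TokenEncoder contract and the full
knowledge bases, both outside this package's scope.

## Problem sizes and runtime

Default test and acceptance runs use 200-document corpora, ~30-token
abstracts, 8 tagger epochs and 25 extractor epochs; the whole test suite
runs in about a minute and `scripts/acceptance.py` in under a minute on
one CPU. These sizes were chosen so every experiment is comfortably
re-runnable during development; all of them scale linearly if larger
studies are wanted.
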