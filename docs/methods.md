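# Methods

## The extraction model

`triplecast` extracts (subject, relation, object) facts from annotated
sentences by reading each sentence twice, conditioning the second pass on
the first:

1. **Subject recognition.** A shared token encoder produces one context
   vector `x_i` per token. An affine map turns these into per-tag emission
   scores over a BIOE alphabet (`B-t`/`I-t`/`E-t` per entity type `t`, plus
   `O`; 19 tags for the six default types), and a linear-chain CRF scores a
   tag sequence `y` as

       S(x, y) = start[y_1] + Σ_i A[y_i, y_{i+1}] + Σ_i P[i, y_i] + stop[y_n]

   with a learned transition matrix `A` and explicit start/stop boundary
   vectors. Decoding is exact Viterbi; every decoded entity span is a
   candidate subject.

2. **Relation-object detection.** Each relation `r` in the closed relation
   inventory owns two affine heads over the fused per-token feature

       h_i = x_i + l_sub + v_i

   where `l_sub` is the subject-label vector (the sum of the label
   embeddings of the subject's own tags, e.g. `l_B-FRU + l_I-FRU +
   l_E-FRU` for a three-token fruit entity) and `v_i` is the
   character-label vector of position `i` (the label embedding of its
   tag). The heads give `p_start[i] = σ(W_start_r · h_i + b_start_r)` and
   `p_end[i] = σ(W_end_r · h_i + b_end_r)`. Positions whose probability
   reaches the detection threshold are flagged; each start flag pairs with
   the nearest end flag at or after it (a position may be both, giving a
   one-token object), and every (subject, relation, object-span) detection
   becomes a triplet.

Because all relations are scored for every candidate subject, a subject
with several objects (single-entity overlap, SEO) and a pair linked by
several relations (entity-pair overlap, EPO) decode naturally — the model
treats each relation as a function mapping subjects to objects rather than
classifying one relation per entity pair.

Both label-embedding pathways share one trainable table: a base vector per
tag pushed through a shared affine map. Either pathway can be ablated
(`use_subject_label`, `use_char_label`) to measure its contribution.

## Assumptions

- Entities are contiguous, non-nested token spans; the relation and entity
  inventories are closed and fixed before training.
- A single-token entity is tagged with a lone `B-t` (the BIOE alphabet has
  no single-token marker); span extraction treats a `B-t` whose run never
  closes as a complete one-token entity and drops orphan `I`/`E` tags
  rather than repairing them.
- Object spans are untyped: the binary taggers predict boundaries only.
  For reporting, an object span that coincides with a CRF-predicted entity
  inherits its type; strict evaluation compares object boundaries plus the
  relation, and subject boundaries plus the subject's entity type.
- Sentence-level overlap categories are non-exclusive: a sentence can be
  both SEO and EPO and is then scored in both breakdown rows.

## Training

The loss is the unit-weighted sum of the two sections: the CRF negative
log-likelihood of the gold tag sequence (partition function by the forward
algorithm in log space) and binary cross-entropy over both heads of every
relation for every candidate subject, averaged per sentence. The printed
form of the tagger objective in some descriptions of this architecture is
not a proper cross-entropy; the standard BCE is the coherent reading and is
what is implemented. Probabilities are clamped to `[1e-7, 1 - 1e-7]`
inside the loss, which keeps it finite without moving its minimizers.

Training uses teacher forcing: gold tags supply `v_i` and gold spans supply
the candidate subjects. Gold spans that are never subjects enter the tagger
batch with all-zero targets, so the taggers also learn to reject the
non-subject candidates the CRF will surface at inference. For each gold
subject all relations are scored, and positions without a gold object are
negative examples. At inference the cascade runs on its own predictions.

Optimization is Adam on shuffled minibatches. The best parameters by
validation strict F1 are kept; training stops early once validation F1
reaches 1.0 (no improvement is possible) or, optionally, after `patience`
epochs without improvement.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `dim` | 64 | width of token encodings and label embeddings (fused by elementwise sum, so the two widths are equal by construction) |
| `batch_size` | 32 | sentences per optimization step |
| `max_len` | 100 | tokens kept per sentence; longer inputs are truncated |
| `dropout` | 0.2 | applied to the encoder output during training |
| `learning_rate` | 0.01 | Adam step size for the desk-scale encoder |
| `epochs` | 50 | maximum training epochs |
| `threshold` | 0.86 | shared start/end flag threshold of the object taggers |
| `use_subject_label` / `use_char_label` | on | ablation switches for the two label-feature pathways |

The same threshold gates start and end flags; raising it can only suppress
detections, so the emitted triplet count is non-increasing in the
threshold (a property the tests exercise).

## The encoder

The desk-scale encoder is a trainable embedding table followed by a
contextualizer with two pathways: a local window (the previous and next
token embeddings enter the output projection) and a global single-head
scaled dot-product attention summary. The local pathway carries the
entity-boundary evidence that BIOE emissions and start/end tagging need;
the global pathway carries sentence-level evidence such as which relation
cue tokens are present. Padded positions are masked out of attention, the
padding embedding row is pinned to zero, and disabling the contextualizer
makes the encoding of token *i* depend only on token *i* (an ablation hook
the tests use). Any encoder honouring the same contract — one finite
d-vector per kept token, differentiable in its parameters — can be dropped
in behind the same interface.

## The synthetic corpus generator

The generator emulates the *structure* of a fruit-nutrition annotation
corpus: six entity types (FRU, SEC, NUT, PER, SYM, LOC), eight relations
(belong, rich_in, favorable, unfavorable, phase_generated, compatible,
origin, process), sentences well under 100 tokens, and a configurable
Normal/SEO/EPO sentence mix, default 60/25/15 — i.e. 40% overlapping
sentences, comfortably above the one-third share that motivates
overlap-aware extraction. Each entity type owns a disjoint abstract
sub-vocabulary and each relation a cue token; relations carry fixed
(subject-type, object-type) signatures, with three signature-sharing pairs
(favorable/unfavorable, phase_generated/compatible, origin/process)
hosting the EPO templates. Same-type entities are always separated by at
least one non-entity token so that span boundaries remain decodable, and
every draw descends from one seeded generator, making corpora reproducible
byte for byte.

What the generator does **not** emulate: real linguistic variation,
ambiguous or multi-word relation cues, annotation noise, distant-
supervision artifacts, type-ambiguous surface forms, and nested or
discontinuous mentions. Passing the recovery tests therefore shows that
the cascade can learn the subject-to-object mappings and decode
overlapping structures when the signal is present — it does not certify
performance on natural text, where a pretrained contextual encoder would
carry most of the weight.

## Numerical choices

- All model arithmetic runs on a compact reverse-mode automatic
  differentiation core over numpy arrays (`triplecast.autodiff`); analytic
  gradients are validated against central finite differences in the test
  suite, including through the CRF forward recursion.
- Log-sum-exp reductions subtract the running maximum, keeping the forward
  algorithm stable at large score scales.
- Viterbi ties break toward the lowest tag id at every backtrack step, so
  decoding is deterministic.
- CRF transitions are unconstrained; BIOE validity is enforced at span
  extraction (malformed runs are dropped deterministically), not during
  decoding.
- Train/validation/test partition is 7:2:1 by sentence after a seeded
  shuffle.
- Checkpoints store schema, vocabulary, configuration and all parameter
  arrays in one `.npz` file; a reloaded model reproduces predictions token
  for token.

## Problem sizes used in tests and the acceptance script

The reference corpus is 2,000 sentences (1,400 train / 400 validation /
200 test) with the default 60/25/15 mix; the full cascade at `dim=64`
typically reaches validation F1 1.0 within ~20 epochs there, and training
stops at that point. Unit and property tests run on corpora of 4–120
sentences and on exhaustively enumerable CRF instances (sequence length
≤ 6, alphabet ≤ 5), where brute force is exact.

## Known limitations

- Teacher forcing means the tagger stage never sees CRF *errors* during
  training; with an imperfect subject recognizer, error propagation at
  inference is unmitigated.
- Objects receive no predicted type of their own.
- The nearest start/end pairing cannot represent nested or crossing object
  spans flagged under the same relation.
- The desk-scale encoder has no pretraining and no positional encoding
  beyond the one-token local window; long-range order information (beyond
  presence of cue tokens) is not represented.
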