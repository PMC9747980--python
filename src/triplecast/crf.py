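"""Linear-chain CRF subject recognizer and the label-embedding table.

A sentence's encoder output is projected to per-position tag scores
(emissions); a learned transition matrix scores adjacent tag pairs.  The
score of a tag sequence y is

    S(x, y) = start[y_1] + sum_i A[y_i, y_{i+1}] + sum_i P[i, y_i] + stop[y_n]

with dedicated start/stop vectors making the boundary terms explicit.
Decoding is Viterbi (ties broken toward the lowest tag id); training
minimizes the negative log-likelihood, whose partition function is computed
by the forward algorithm in log space.  Candidate subjects are read off the
decoded BIOE sequence; each carries the tag ids composing it, which index
the label-embedding table.

The label-embedding table realizes the hybrid label features: a trainable
base vector per tag pushed through a shared affine map.  Looking up each
position's tag gives the character-label vectors ``v_i``; summing a
subject's tag vectors gives its subject-label vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, embedding, logsumexp, where
from .schema import Span, TagSet, extract_spans

__all__ = ["CrfParams", "LabelEmbeddingTable", "SubjectCandidate",
           "crf_score", "viterbi_decode", "crf_nll", "crf_nll_batch",
           "lookup_char_labels", "candidate_subjects"]


@dataclass
class CrfParams:
    """Transition structure and emission projection of the CRF.

    ``transitions[i, j]`` is the score of moving from tag *i* to tag *j*;
    ``start``/``stop`` score a sequence beginning/ending in a tag.  The
    affine map (``W_emit``, ``b_emit``) turns d-dim context vectors into
    per-tag emission scores.
    """

    n_tags: int
    dim: int
    rng: np.random.Generator | None = None
    transitions: Tensor = field(init=False)
    start: Tensor = field(init=False)
    stop: Tensor = field(init=False)
    W_emit: Tensor = field(init=False)
    b_emit: Tensor = field(init=False)

    def __post_init__(self):
        rng = self.rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(self.dim)
        self.transitions = Tensor(rng.normal(0, 0.01, (self.n_tags, self.n_tags)),
                                  requires_grad=True)
        self.start = Tensor(np.zeros(self.n_tags), requires_grad=True)
        self.stop = Tensor(np.zeros(self.n_tags), requires_grad=True)
        self.W_emit = Tensor(rng.normal(0, s, (self.dim, self.n_tags)),
                             requires_grad=True)
        self.b_emit = Tensor(np.zeros(self.n_tags), requires_grad=True)

    def emissions(self, vectors: Tensor) -> Tensor:
        """Project context vectors (..., d) to tag scores (..., n_tags)."""
        return vectors @ self.W_emit + self.b_emit

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return [("crf.transitions", self.transitions),
                ("crf.start", self.start),
                ("crf.stop", self.stop),
                ("crf.W_emit", self.W_emit),
                ("crf.b_emit", self.b_emit)]


def _check_lengths(emissions: np.ndarray, tags) -> None:
    if len(tags) != emissions.shape[0]:
        raise ValueError(
            f"tag sequence length {len(tags)} != emission rows {emissions.shape[0]}")


def crf_score(emissions: np.ndarray, params: CrfParams, tags) -> float:
    """Score one tag sequence: boundary + transition + emission terms."""
    emissions = np.asarray(emissions, dtype=float)
    tags = np.asarray(tags, dtype=int)
    if tags.size == 0:
        raise ValueError("empty tag sequence")
    _check_lengths(emissions, tags)
    A = params.transitions.data
    score = params.start.data[tags[0]] + params.stop.data[tags[-1]]
    score += emissions[np.arange(len(tags)), tags].sum()
    score += A[tags[:-1], tags[1:]].sum()
    return float(score)


def viterbi_decode(emissions: np.ndarray, params: CrfParams) -> list[int]:
    """Highest-scoring tag sequence under :func:`crf_score`.

    Deterministic: at every backtrack step ties are broken toward the
    lowest tag id (``argmax`` keeps the first maximizer).
    """
    emissions = np.asarray(emissions, dtype=float)
    n = emissions.shape[0]
    if n == 0:
        raise ValueError("cannot decode an empty sequence")
    A = params.transitions.data
    delta = params.start.data + emissions[0]
    backptr = np.zeros((n, emissions.shape[1]), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + A  # (from, to)
        backptr[t] = np.argmax(cand, axis=0)
        delta = cand[backptr[t], np.arange(cand.shape[1])] + emissions[t]
    delta = delta + params.stop.data
    best = int(np.argmax(delta))
    path = [best]
    for t in range(n - 1, 0, -1):
        best = int(backptr[t, best])
        path.append(best)
    return path[::-1]


def crf_nll_batch(emissions: Tensor, tags: np.ndarray, mask: np.ndarray,
                  params: CrfParams) -> Tensor:
    """Per-sequence negative log-likelihood for a padded batch.

    ``emissions`` is (B, T, K), ``tags`` (B, T) gold ids, ``mask`` (B, T)
    validity.  Returns a (B,) tensor ``log Z - S(x, gold)``; non-negative
    because the log partition dominates every single path score.
    """
    B, T, K = emissions.shape
    tags = np.asarray(tags, dtype=np.intp)
    if tags.shape != (B, T):
        raise ValueError(f"gold tags shape {tags.shape} != {(B, T)}")
    if tags.min() < 0 or tags.max() >= K:
        raise ValueError("gold tag id out of range")
    A = params.transitions
    lengths = mask.sum(axis=1).astype(np.intp)

    # forward algorithm in log space; alpha frozen past each sequence's end
    alpha = params.start + emissions[:, 0, :]
    for t in range(1, T):
        scores = alpha.reshape(B, K, 1) + A.reshape(1, K, K) \
            + emissions[:, t, :].reshape(B, 1, K)
        new = logsumexp(scores, axis=1)
        alpha = where(mask[:, t][:, None], new, alpha)
    log_z = logsumexp(alpha + params.stop, axis=1)

    b_idx = np.arange(B)
    em_gold = emissions[b_idx[:, None], np.arange(T)[None, :], tags]
    gold = (em_gold * mask).sum(axis=1)
    if T > 1:
        tr_gold = A[tags[:, :-1], tags[:, 1:]]
        gold = gold + (tr_gold * mask[:, 1:]).sum(axis=1)
    gold = gold + params.start[tags[:, 0]] + params.stop[tags[b_idx, lengths - 1]]
    return log_z - gold


def crf_nll(emissions: Tensor, params: CrfParams, gold_tags) -> Tensor:
    """Negative log-likelihood of one gold tag sequence (scalar tensor)."""
    if not isinstance(emissions, Tensor):
        emissions = Tensor(emissions)
    n, k = emissions.shape
    tags = np.asarray(gold_tags, dtype=np.intp)[None, :]
    mask = np.ones((1, n), dtype=bool)
    return crf_nll_batch(emissions.reshape(1, n, k), tags, mask, params).sum()


@dataclass
class LabelEmbeddingTable:
    """Trainable vector per tag, shared by both label-feature pathways."""

    n_tags: int
    dim: int
    rng: np.random.Generator | None = None
    base: Tensor = field(init=False)
    W_l: Tensor = field(init=False)
    b_l: Tensor = field(init=False)

    def __post_init__(self):
        rng = self.rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(self.dim)
        self.base = Tensor(rng.normal(0, s, (self.n_tags, self.dim)),
                           requires_grad=True)
        self.W_l = Tensor(np.eye(self.dim) + rng.normal(0, 0.01, (self.dim, self.dim)),
                          requires_grad=True)
        self.b_l = Tensor(np.zeros(self.dim), requires_grad=True)

    def rows(self) -> Tensor:
        """The full label matrix: base embeddings through the affine map."""
        return self.base @ self.W_l + self.b_l

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return [("labels.base", self.base),
                ("labels.W_l", self.W_l),
                ("labels.b_l", self.b_l)]


def lookup_char_labels(tag_ids: np.ndarray, table: LabelEmbeddingTable) -> Tensor:
    """Character-label vectors ``v_i``: one table row per position's tag."""
    tag_ids = np.asarray(tag_ids, dtype=np.intp)
    return table.rows()[tag_ids]


@dataclass(frozen=True)
class SubjectCandidate:
    """A decoded entity span plus the tag ids that spelled it out."""

    span: Span
    tag_ids: tuple[int, ...]


def candidate_subjects(tags: list[str], tagset: TagSet) -> list[SubjectCandidate]:
    """All entity spans decodable from a BIOE tag sequence, as candidates."""
    out = []
    for sp in extract_spans(tags):
        ids = tuple(tagset.index_of(tags[i]) for i in sp.positions())
        out.append(SubjectCandidate(span=sp, tag_ids=ids))
    return out
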