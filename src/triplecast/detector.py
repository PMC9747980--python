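"""Per-relation binary start/end object taggers and triplet assembly.

Each predefined relation *r* owns two affine heads over the fused per-token
feature ``x_i + l_sub + v_i`` (context vector + subject-label vector +
character-label vector):

    p_start[i] = sigmoid(W_start_r . h_i + b_start_r)
    p_end[i]   = sigmoid(W_end_r   . h_i + b_end_r)

Positions whose probability reaches the detection threshold (default 0.86)
are flagged; each start flag pairs with the nearest end flag at or after it
(ends consumed left to right), a position may be both start and end of a
one-token object, and unmatched starts are dropped.  Running every relation
for every candidate subject makes one subject with several objects (SEO) and
one pair under several relations (EPO) fall out naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, sigmoid
from .crf import LabelEmbeddingTable, SubjectCandidate
from .schema import RelationSchema, Span, Triplet, UNTYPED

__all__ = ["RelationTaggerParams", "ObjectProbabilities", "DetectionConfig",
           "subject_label_vector", "tag_objects", "tag_objects_all_relations",
           "match_spans", "assemble_triplets"]


@dataclass(frozen=True)
class DetectionConfig:
    """Span-decoding settings; one shared threshold flags starts and ends."""

    threshold: float = 0.86

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass
class RelationTaggerParams:
    """Stacked start/end heads, one row per relation in schema order."""

    relations: RelationSchema
    dim: int
    rng: np.random.Generator | None = None
    W_start: Tensor = field(init=False)
    b_start: Tensor = field(init=False)
    W_end: Tensor = field(init=False)
    b_end: Tensor = field(init=False)

    def __post_init__(self):
        rng = self.rng or np.random.default_rng(0)
        R = len(self.relations)
        s = 1.0 / np.sqrt(self.dim)
        self.W_start = Tensor(rng.normal(0, s, (R, self.dim)), requires_grad=True)
        self.b_start = Tensor(np.zeros(R), requires_grad=True)
        self.W_end = Tensor(rng.normal(0, s, (R, self.dim)), requires_grad=True)
        self.b_end = Tensor(np.zeros(R), requires_grad=True)

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return [("tagger.W_start", self.W_start),
                ("tagger.b_start", self.b_start),
                ("tagger.W_end", self.W_end),
                ("tagger.b_end", self.b_end)]


@dataclass
class ObjectProbabilities:
    """Per-position start/end probabilities for one (subject, relation)."""

    p_start: np.ndarray
    p_end: np.ndarray

    def __post_init__(self):
        if self.p_start.shape != self.p_end.shape:
            raise ValueError("start/end probability shapes differ")


def subject_label_vector(subject: SubjectCandidate,
                         table: LabelEmbeddingTable) -> Tensor:
    """Sum of the label-embedding rows of the subject's tags.

    A three-token FRU subject yields ``l_B-FRU + l_I-FRU + l_E-FRU``; a
    one-token subject yields its single B-tag row.
    """
    ids = np.asarray(subject.tag_ids, dtype=np.intp)
    return table.rows()[ids].sum(axis=0)


def _fuse(x: Tensor, l_sub: Tensor | None, v: Tensor | None) -> Tensor:
    h = x
    if l_sub is not None:
        h = h + l_sub  # broadcasts (d,) over (n, d)
    if v is not None:
        h = h + v
    return h


def tag_objects(x: Tensor, l_sub: Tensor | None, v: Tensor | None,
                params: RelationTaggerParams, relation: str) -> ObjectProbabilities:
    """Start/end probabilities for one subject under one relation."""
    probs = tag_objects_all_relations(x, l_sub, v, params)
    r = params.relations.index(relation)
    return ObjectProbabilities(p_start=probs[0].data[:, r],
                               p_end=probs[1].data[:, r])


def tag_objects_all_relations(x: Tensor, l_sub: Tensor | None,
                              v: Tensor | None,
                              params: RelationTaggerParams) -> tuple[Tensor, Tensor]:
    """Start/end probability tensors (n, R) across every relation at once."""
    if v is not None and v.shape != x.shape:
        raise ValueError(f"character-label shape {v.shape} != encoding {x.shape}")
    if l_sub is not None and l_sub.shape[-1] != x.shape[-1]:
        raise ValueError("subject-label dimension differs from encoder dimension")
    h = _fuse(x, l_sub, v)
    p_start = sigmoid(h @ params.W_start.T + params.b_start)
    p_end = sigmoid(h @ params.W_end.T + params.b_end)
    return p_start, p_end


def match_spans(probs: ObjectProbabilities, cfg: DetectionConfig,
                obj_type_map: dict[tuple[int, int], str] | None = None) -> list[Span]:
    """Decode flagged positions into object spans by nearest-pair matching.

    Every position with ``p_start >= threshold`` opens a span; it pairs with
    the nearest unconsumed position at or after it where ``p_end >=
    threshold`` (the same position closes a one-token object).  Starts with
    no remaining end are dropped.  ``obj_type_map`` optionally attaches an
    entity type to spans whose boundaries coincide with a typed prediction;
    others are reported as UNTYPED.
    """
    starts = np.flatnonzero(probs.p_start >= cfg.threshold)
    ends = np.flatnonzero(probs.p_end >= cfg.threshold)
    spans: list[Span] = []
    used_end = 0  # ends are consumed left to right
    for s in starts:
        while used_end < len(ends) and ends[used_end] < s:
            used_end += 1
        if used_end == len(ends):
            break
        e = int(ends[used_end])
        used_end += 1
        typ = UNTYPED
        if obj_type_map is not None:
            typ = obj_type_map.get((int(s), e + 1), UNTYPED)
        spans.append(Span(int(s), e + 1, typ))
    return spans


def assemble_triplets(
    detections: list[tuple[SubjectCandidate, str, list[Span]]],
) -> list[Triplet]:
    """Flatten per-(subject, relation) object spans into deduplicated triplets.

    Duplicate facts (same subject span and type, relation, object
    boundaries) collapse to one; order of first appearance is kept.
    """
    seen: set[tuple] = set()
    out: list[Triplet] = []
    for subject, relation, spans in detections:
        for obj in spans:
            key = (subject.span.start, subject.span.end, subject.span.type,
                   relation, obj.start, obj.end)
            if key in seen:
                continue
            seen.add(key)
            out.append(Triplet(subject=subject.span, relation=relation, object=obj))
    return out
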