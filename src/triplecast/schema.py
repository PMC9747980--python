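"""Entity types, relations, the BIOE tag alphabet and overlap categories.

The extraction task operates over a closed schema: a fixed, ordered set of
entity type codes (e.g. ``FRU`` for fruit, ``NUT`` for nutrient) and a fixed,
ordered set of relation names.  Token-level supervision uses the BIOE scheme:
``B-t``/``I-t``/``E-t`` mark the beginning, interior and end of an entity of
type ``t``, and ``O`` marks a non-entity token, giving ``3 * n_types + 1``
tags in total.

Sentences are classified by how their gold triplets overlap:

* ``NORMAL`` — no entity is shared between triplets;
* ``SEO`` (single-entity overlap) — one entity participates in two or more
  triplets with different counterparts;
* ``EPO`` (entity-pair overlap) — the same (subject, object) pair is linked
  by two or more distinct relations.

Span indices are 0-based and half-open: ``Span(start, end)`` covers tokens
``start .. end - 1`` and has length ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SchemaError",
    "AnnotationError",
    "EntityTypeSet",
    "TagSet",
    "RelationSchema",
    "Span",
    "Triplet",
    "NORMAL",
    "SEO",
    "EPO",
    "UNTYPED",
    "build_tagset",
    "spans_to_tags",
    "extract_spans",
    "classify_overlap",
]

NORMAL = "NORMAL"
SEO = "SEO"
EPO = "EPO"

#: Type code attached to decoded object spans that do not coincide with a
#: typed entity prediction; object typing is reporting-only.
UNTYPED = "UNTYPED"


class SchemaError(ValueError):
    """Invalid entity-type or relation schema."""


class AnnotationError(ValueError):
    """Inconsistent span/tag annotation (overlaps, out-of-range offsets)."""


@dataclass(frozen=True)
class EntityTypeSet:
    """Ordered, duplicate-free collection of entity type codes."""

    types: tuple[str, ...]

    def __init__(self, types: Iterable[str]):
        object.__setattr__(self, "types", tuple(types))
        if len(set(self.types)) != len(self.types):
            raise SchemaError(f"duplicate entity type codes in {self.types!r}")
        if any(not t for t in self.types):
            raise SchemaError("entity type codes must be non-empty strings")

    def __iter__(self):
        return iter(self.types)

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, code: str) -> bool:
        return code in self.types


@dataclass(frozen=True)
class RelationSchema:
    """Ordered, duplicate-free collection of relation names.

    The order is load-bearing: it indexes the per-relation tagger
    parameters, so it is serialized with every model checkpoint.
    """

    relations: tuple[str, ...]

    def __init__(self, relations: Iterable[str]):
        object.__setattr__(self, "relations", tuple(relations))
        if len(set(self.relations)) != len(self.relations):
            raise SchemaError(f"duplicate relation names in {self.relations!r}")
        if any(not r for r in self.relations):
            raise SchemaError("relation names must be non-empty strings")

    def __iter__(self):
        return iter(self.relations)

    def __len__(self) -> int:
        return len(self.relations)

    def __contains__(self, name: str) -> bool:
        return name in self.relations

    def index(self, name: str) -> int:
        return self.relations.index(name)


@dataclass(frozen=True)
class TagSet:
    """BIOE tag alphabet: ``O`` first, then ``B-t``, ``I-t``, ``E-t`` per type."""

    tags: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tags)})

    def index_of(self, tag: str) -> int:
        return self._index[tag]

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._index

    @property
    def outside_id(self) -> int:
        return self._index["O"]


@dataclass(frozen=True, order=True)
class Span:
    """Half-open token span ``[start, end)`` with an entity type code."""

    start: int
    end: int
    type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def positions(self) -> range:
        return range(self.start, self.end)


@dataclass(frozen=True, order=True)
class Triplet:
    """A (subject, relation, object) fact anchored to token spans."""

    subject: Span
    relation: str
    object: Span


def build_tagset(entity_types: EntityTypeSet) -> TagSet:
    """Derive the BIOE tag alphabet from an entity type set.

    ``O`` comes first, then ``B-t, I-t, E-t`` for each type in schema order,
    so the alphabet has ``3 * len(entity_types) + 1`` tags (19 for the six
    fruit-nutrition types).
    """
    tags = ["O"]
    for t in entity_types:
        tags.extend((f"B-{t}", f"I-{t}", f"E-{t}"))
    return TagSet(tags=tuple(tags))


def spans_to_tags(spans: Sequence[Span], length: int) -> list[str]:
    """Render non-overlapping spans as a BIOE tag sequence of ``length``.

    A span of length >= 2 becomes ``B-t, I-t ..., E-t``; a single-token span
    becomes a lone ``B-t`` (the alphabet has no single-token marker, and a
    lone ``B-t`` round-trips through :func:`extract_spans`).
    """
    tags = ["O"] * length
    occupied = [False] * length
    for sp in spans:
        if sp.end > length:
            raise AnnotationError(f"span {sp} exceeds sentence length {length}")
        if any(occupied[i] for i in sp.positions()):
            raise AnnotationError(f"span {sp} overlaps another span")
        for i in sp.positions():
            occupied[i] = True
        if len(sp) == 1:
            tags[sp.start] = f"B-{sp.type}"
        else:
            tags[sp.start] = f"B-{sp.type}"
            for i in range(sp.start + 1, sp.end - 1):
                tags[i] = f"I-{sp.type}"
            tags[sp.end - 1] = f"E-{sp.type}"
    return tags


def extract_spans(tags: Sequence[str]) -> list[Span]:
    """Decode a BIOE tag sequence into typed spans.

    Well-formed runs are ``B-t [I-t]* E-t`` and the lone ``B-t`` (one-token
    entity).  Malformed runs — ``I``/``E`` without a ``B``, a type switch
    mid-entity, a ``B`` whose run never closes before another ``B`` or the
    sentence end — contribute the longest valid prefix interpretation:
    a dangling ``B-t`` still yields its one-token entity, while orphan
    ``I``/``E`` tags are dropped, never repaired.
    """
    spans: list[Span] = []
    i, n = 0, len(tags)
    while i < n:
        tag = tags[i]
        if tag.startswith("B-"):
            t = tag[2:]
            j = i + 1
            while j < n and tags[j] == f"I-{t}":
                j += 1
            if j < n and tags[j] == f"E-{t}":
                spans.append(Span(i, j + 1, t))
                i = j + 1
            else:
                # run never closed: keep the B token as a one-token entity,
                # drop the orphan I tail
                spans.append(Span(i, i + 1, t))
                i = i + 1
        else:
            i += 1
    return spans


def classify_overlap(triplets: Sequence[Triplet]) -> set[str]:
    """Classify a sentence's triplet inventory into overlap categories.

    EPO holds when some (subject-span, object-span) pair carries at least two
    distinct relations.  SEO holds when some entity span occurs in at least
    two triplets that are not mere EPO duplicates of one pair.  NORMAL holds
    when neither does.  Categories are not mutually exclusive across a
    sentence.
    """
    if not triplets:
        raise ValueError("cannot classify an empty triplet list")
    uniq = sorted(set(triplets))

    pair_relations: dict[tuple[Span, Span], set[str]] = {}
    for tr in uniq:
        pair_relations.setdefault((tr.subject, tr.object), set()).add(tr.relation)
    epo = any(len(rs) >= 2 for rs in pair_relations.values())

    # SEO: an entity span shared across >= 2 distinct (subject, object) pairs
    span_pairs: dict[Span, set[tuple[Span, Span]]] = {}
    for tr in uniq:
        for sp in (tr.subject, tr.object):
            span_pairs.setdefault(sp, set()).add((tr.subject, tr.object))
    seo = any(len(pairs) >= 2 for pairs in span_pairs.values())

    cats: set[str] = set()
    if epo:
        cats.add(EPO)
    if seo:
        cats.add(SEO)
    if not cats:
        cats.add(NORMAL)
    return cats
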