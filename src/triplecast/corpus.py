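"""Seeded synthetic corpora with a controllable Normal/SEO/EPO mix.

The generator emulates the structure of a fruit-nutrition annotation corpus
— six entity types, eight relations, short sentences, and a substantial
share of overlapping triplets — without any language resource: surface
tokens are abstract symbols.  Each entity type owns a disjoint sub-vocabulary
(``fru0, fru1, ...``) so types are learnable from token identity, and each
relation owns a trigger token (``cue_origin``) whose presence in the sentence
signals that relation, so the subject-to-object mapping is learnable by a
context-capable encoder.

Templates per sentence category:

* NORMAL — one subject, one trigger, one object: a single triplet.
* SEO — one subject with two distinct objects, either under one repeated
  relation or under two relations with different object types.
* EPO — one subject, two triggers from a relation group sharing the same
  type signature, one object: the same pair under two relations.

Sampling a category per sentence from ``overlap_mix`` makes empirical
category fractions converge to the mix.  Every draw flows from one
``numpy`` generator seeded by the config, so corpora are reproducible
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import (EPO, NORMAL, SEO, EntityTypeSet, RelationSchema, Span,
                     Triplet, classify_overlap, spans_to_tags)

__all__ = ["CorpusConfig", "CorpusExample", "generate_corpus", "corpus_stats",
           "split_corpus", "validate_example", "DEFAULT_ENTITY_TYPES",
           "DEFAULT_RELATIONS", "DEFAULT_SIGNATURES", "ConfigError"]


class ConfigError(ValueError):
    """Invalid corpus configuration."""


#: Entity classes of the fruit-nutrition domain: fruit, science (taxon),
#: nutrient, person/crowd, symptom, location.
DEFAULT_ENTITY_TYPES = EntityTypeSet(["FRU", "SEC", "NUT", "PER", "SYM", "LOC"])

#: The eight fruit-nutrition relation categories.
DEFAULT_RELATIONS = RelationSchema([
    "belong", "rich_in", "favorable", "unfavorable",
    "phase_generated", "compatible", "origin", "process",
])

#: (subject type, object type) per default relation.  Three pairs share a
#: signature — (favorable, unfavorable), (phase_generated, compatible),
#: (origin, process) — and those groups host the EPO templates.
DEFAULT_SIGNATURES: dict[str, tuple[str, str]] = {
    "belong": ("FRU", "SEC"),
    "rich_in": ("FRU", "NUT"),
    "favorable": ("FRU", "SYM"),
    "unfavorable": ("FRU", "SYM"),
    "phase_generated": ("FRU", "PER"),
    "compatible": ("FRU", "PER"),
    "origin": ("FRU", "LOC"),
    "process": ("FRU", "LOC"),
}


@dataclass(frozen=True)
class CorpusConfig:
    n_sentences: int = 2000
    entity_types: EntityTypeSet = DEFAULT_ENTITY_TYPES
    relations: RelationSchema = DEFAULT_RELATIONS
    overlap_mix: tuple[float, float, float] = (0.60, 0.25, 0.15)
    vocab_size: int = 240
    max_len: int = 100
    seed: int = 0
    signatures: dict[str, tuple[str, str]] | None = None

    def __post_init__(self):
        mix = np.asarray(self.overlap_mix, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"overlap_mix must be non-negative and sum to 1, got {self.overlap_mix}")
        if self.max_len < 8:
            raise ConfigError("max_len must be at least 8")
        if self.n_sentences < 1:
            raise ConfigError("need at least one sentence")

    def resolved_signatures(self) -> dict[str, tuple[str, str]]:
        """Type signature per relation; curated for the default schema.

        For custom schemas, relations are paired (2k, 2k+1) onto rotating
        distinct (subject, object) type pairs so every schema with >= 2
        entity types has EPO-capable groups.
        """
        if self.signatures is not None:
            return dict(self.signatures)
        if (self.entity_types == DEFAULT_ENTITY_TYPES
                and self.relations == DEFAULT_RELATIONS):
            return dict(DEFAULT_SIGNATURES)
        types = list(self.entity_types)
        if len(types) < 2:
            raise ConfigError("generation needs at least two entity types")
        sig = {}
        for i, rel in enumerate(self.relations):
            k = i // 2
            sig[rel] = (types[k % len(types)], types[(k + 1) % len(types)])
        return sig


@dataclass
class CorpusExample:
    """One annotated sentence: tokens, typed spans, BIOE tags, triplets."""

    tokens: list[str]
    spans: list[Span]
    tags: list[str]
    triplets: list[Triplet]


def validate_example(ex: CorpusExample, max_len: int = 100) -> None:
    """Check internal consistency; raises ``ValueError`` on violation."""
    if len(ex.tokens) > max_len:
        raise ValueError(f"sentence length {len(ex.tokens)} exceeds {max_len}")
    if ex.tags != spans_to_tags(ex.spans, len(ex.tokens)):
        raise ValueError("tags inconsistent with spans")
    span_set = set(ex.spans)
    for tr in ex.triplets:
        if tr.subject not in span_set or tr.object not in span_set:
            raise ValueError(f"triplet {tr} references a span not in the example")


def _build_pools(cfg: CorpusConfig) -> tuple[dict[str, list[str]], dict[str, str], list[str]]:
    """Partition the vocabulary into per-type pools, triggers and fillers."""
    n_types = len(cfg.entity_types)
    n_rel = len(cfg.relations)
    n_fill = max(4, cfg.vocab_size // 20)
    per_type = (cfg.vocab_size - n_rel - n_fill) // max(n_types, 1)
    if per_type < 4:
        raise ConfigError(
            f"vocab_size {cfg.vocab_size} too small for {n_types} disjoint "
            f"entity pools plus {n_rel} triggers")
    pools = {t: [f"{t.lower()}{i}" for i in range(per_type)]
             for t in cfg.entity_types}
    triggers = {r: f"cue_{r}" for r in cfg.relations}
    fillers = [f"w{i}" for i in range(n_fill)]
    return pools, triggers, fillers


class _SentenceBuilder:
    def __init__(self):
        self.tokens: list[str] = []
        self.spans: list[Span] = []

    def add_tokens(self, toks: list[str]) -> None:
        self.tokens.extend(toks)

    def add_entity(self, surface: list[str], etype: str) -> Span:
        sp = Span(len(self.tokens), len(self.tokens) + len(surface), etype)
        self.tokens.extend(surface)
        self.spans.append(sp)
        return sp


def _entity_surface(rng: np.random.Generator, pool: list[str],
                    max_tokens: int = 3) -> list[str]:
    n = int(rng.integers(1, max_tokens + 1))
    return [pool[int(i)] for i in rng.integers(0, len(pool), size=n)]


def _fillers(rng: np.random.Generator, fillers: list[str], lo=0, hi=2) -> list[str]:
    n = int(rng.integers(lo, hi + 1))
    return [fillers[int(i)] for i in rng.integers(0, len(fillers), size=n)]


def generate_corpus(cfg: CorpusConfig) -> list[CorpusExample]:
    """Generate ``cfg.n_sentences`` annotated sentences under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    pools, triggers, fillers = _build_pools(cfg)
    sig = cfg.resolved_signatures()
    relations = list(cfg.relations)

    # relation groups sharing a type signature, for EPO templates
    by_sig: dict[tuple[str, str], list[str]] = {}
    for r in relations:
        by_sig.setdefault(sig[r], []).append(r)
    epo_groups = [rs for rs in by_sig.values() if len(rs) >= 2]

    # subject-type groups for SEO templates with two different relations:
    # require distinct object types so the mapping stays learnable from
    # token identity plus sentence context
    by_subj: dict[str, list[str]] = {}
    for r in relations:
        by_subj.setdefault(sig[r][0], []).append(r)

    mix = np.asarray(cfg.overlap_mix, dtype=float)
    if mix[2] > 0 and not epo_groups:
        raise ConfigError("overlap_mix requests EPO but no two relations share "
                          "a type signature")

    # with a tight length budget, shrink entities and drop fillers so no
    # template can overrun max_len (spans are never truncated)
    ent_max = 3 if cfg.max_len >= 20 else 1
    f_hi = 2 if cfg.max_len >= 20 else 0

    examples: list[CorpusExample] = []
    for _ in range(cfg.n_sentences):
        cat = ("normal", "seo", "epo")[int(rng.choice(3, p=mix))]
        b = _SentenceBuilder()
        b.add_tokens(_fillers(rng, fillers, 0, f_hi))
        triplets: list[Triplet] = []

        if cat == "normal":
            r = relations[int(rng.integers(len(relations)))]
            st, ot = sig[r]
            subj = b.add_entity(_entity_surface(rng, pools[st], ent_max), st)
            b.add_tokens(_fillers(rng, fillers, 0, min(1, f_hi)))
            b.add_tokens([triggers[r]])
            obj = b.add_entity(_entity_surface(rng, pools[ot], ent_max), ot)
            triplets.append(Triplet(subj, r, obj))

        elif cat == "seo":
            st = str(rng.choice(sorted(by_subj)))
            group = by_subj[st]
            r1 = group[int(rng.integers(len(group)))]
            distinct = [r for r in group if sig[r][1] != sig[r1][1]]
            if distinct and rng.random() < 0.5:
                r2 = distinct[int(rng.integers(len(distinct)))]
            else:
                r2 = r1  # one relation, two objects
            subj = b.add_entity(_entity_surface(rng, pools[st], ent_max), st)
            b.add_tokens([triggers[r1]])
            o1 = b.add_entity(_entity_surface(rng, pools[sig[r1][1]], ent_max), sig[r1][1])
            if r2 != r1:
                b.add_tokens(_fillers(rng, fillers, 0, min(1, f_hi)))
                b.add_tokens([triggers[r2]])
            else:
                # same relation, two objects: a filler keeps same-type
                # entities from abutting, so span boundaries stay decodable
                b.add_tokens(_fillers(rng, fillers, 1, max(1, f_hi)))
            o2 = b.add_entity(_entity_surface(rng, pools[sig[r2][1]], ent_max), sig[r2][1])
            triplets.append(Triplet(subj, r1, o1))
            triplets.append(Triplet(subj, r2, o2))

        else:  # epo
            group = epo_groups[int(rng.integers(len(epo_groups)))]
            idx = rng.permutation(len(group))[:2]
            r1, r2 = group[int(idx[0])], group[int(idx[1])]
            st, ot = sig[r1]
            subj = b.add_entity(_entity_surface(rng, pools[st], ent_max), st)
            b.add_tokens(_fillers(rng, fillers, 0, min(1, f_hi)))
            b.add_tokens([triggers[r1], triggers[r2]])
            obj = b.add_entity(_entity_surface(rng, pools[ot], ent_max), ot)
            triplets.append(Triplet(subj, r1, obj))
            triplets.append(Triplet(subj, r2, obj))

        b.add_tokens(_fillers(rng, fillers, 0, f_hi))
        tokens = b.tokens[: cfg.max_len]
        ex = CorpusExample(tokens=tokens, spans=b.spans,
                           tags=spans_to_tags(b.spans, len(tokens)),
                           triplets=triplets)
        validate_example(ex, cfg.max_len)
        examples.append(ex)
    return examples


def corpus_stats(corpus: list[CorpusExample]) -> dict:
    """Counts per entity type, relation and overlap category.

    Overlap categories are not mutually exclusive, so their sentence counts
    may sum to more than the number of sentences.
    """
    if not corpus:
        raise ValueError("empty corpus")
    ent: dict[str, int] = {}
    rel: dict[str, int] = {}
    cat = {NORMAL: 0, SEO: 0, EPO: 0}
    n_triplets = 0
    for ex in corpus:
        for sp in ex.spans:
            ent[sp.type] = ent.get(sp.type, 0) + 1
        for tr in ex.triplets:
            rel[tr.relation] = rel.get(tr.relation, 0) + 1
            n_triplets += 1
        if ex.triplets:
            for c in classify_overlap(ex.triplets):
                cat[c] += 1
    return {
        "n_sentences": len(corpus),
        "n_triplets": n_triplets,
        "entity_types": dict(sorted(ent.items())),
        "relations": dict(sorted(rel.items())),
        "overlap_categories": cat,
        "overlap_fraction": (cat[SEO] + cat[EPO]
                             - sum(1 for ex in corpus if ex.triplets
                                   and classify_overlap(ex.triplets) >= {SEO, EPO}))
        / len(corpus),
    }


def split_corpus(corpus: list[CorpusExample], seed: int,
                 ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                 ) -> tuple[list[CorpusExample], list[CorpusExample], list[CorpusExample]]:
    """Shuffle under ``seed`` and split into train/validation/test."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(ratios[0] * len(corpus)))
    n_val = int(round(ratios[1] * len(corpus)))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return ([corpus[i] for i in idx_train],
            [corpus[i] for i in idx_val],
            [corpus[i] for i in idx_test])
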