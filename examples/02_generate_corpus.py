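"""Seeded synthetic corpus generation with a controlled overlap mix.

Generates 500 annotated sentences where 60% carry one plain triplet, 25%
are single-entity-overlap (one subject, several objects) and 15% are
entity-pair-overlap (one pair, several relations), then prints the corpus
summary and one sentence of each kind.
"""

from triplecast import (CorpusConfig, classify_overlap, corpus_stats,
                        generate_corpus)

cfg = CorpusConfig(n_sentences=500, overlap_mix=(0.60, 0.25, 0.15), seed=7)
corpus = generate_corpus(cfg)
stats = corpus_stats(corpus)

print(f"sentences: {stats['n_sentences']}, triplets: {stats['n_triplets']}")
print(f"overlapping sentences: {100 * stats['overlap_fraction']:.1f}% "
      f"(mix asked for {100 * (cfg.overlap_mix[1] + cfg.overlap_mix[2]):.0f}%)")
print("triplets per relation:", stats["relations"])

shown = set()
for ex in corpus:
    cat = "+".join(sorted(classify_overlap(ex.triplets)))
    if cat in shown:
        continue
    shown.add(cat)
    print(f"\n[{cat}] {' '.join(ex.tokens)}")
    for t in ex.triplets:
        subj = " ".join(ex.tokens[t.subject.start:t.subject.end])
        obj = " ".join(ex.tokens[t.object.start:t.object.end])
        print(f"  ({subj}, {t.relation}, {obj})")
    if len(shown) == 3:
        break

# Entity surface tokens are drawn from disjoint per-type pools (fru*, loc*,
# ...) and each relation is signalled by its cue token, so the mapping from
# subject to object under each relation is learnable from the annotation.
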