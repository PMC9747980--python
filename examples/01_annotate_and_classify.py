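"""Span annotation, BIOE tagging and overlap classification.

Builds the three canonical fruit-nutrition sentences by hand — one plain
fact, one subject shared by two objects (SEO), one entity pair carrying two
relations (EPO) — and shows the tag sequences and the overlap category each
sentence falls into.
"""

from triplecast import (EntityTypeSet, Span, Triplet, build_tagset,
                        classify_overlap, extract_spans, spans_to_tags)

types = EntityTypeSet(["FRU", "SEC", "NUT", "PER", "SYM", "LOC"])
tagset = build_tagset(types)
print(f"{len(types)} entity types -> {len(tagset)} BIOE tags")

sentences = [
    ("Kiwifruit belongs to Actinidiaceae".split(),
     [Span(0, 1, "FRU"), Span(3, 4, "SEC")],
     [Triplet(Span(0, 1, "FRU"), "belong", Span(3, 4, "SEC"))]),
    ("Kiwifruit is rich in vitamin C and grape acid".split(),
     [Span(0, 1, "FRU"), Span(4, 6, "NUT"), Span(7, 9, "NUT")],
     [Triplet(Span(0, 1, "FRU"), "rich_in", Span(4, 6, "NUT")),
      Triplet(Span(0, 1, "FRU"), "rich_in", Span(7, 9, "NUT"))]),
    ("Kiwifruit is mainly processed and produced in Shaanxi".split(),
     [Span(0, 1, "FRU"), Span(7, 8, "LOC")],
     [Triplet(Span(0, 1, "FRU"), "origin", Span(7, 8, "LOC")),
      Triplet(Span(0, 1, "FRU"), "process", Span(7, 8, "LOC"))]),
]

for tokens, spans, triplets in sentences:
    tags = spans_to_tags(spans, len(tokens))
    assert extract_spans(tags) == spans  # tagging round-trips
    cats = classify_overlap(triplets)
    print()
    print(" ".join(tokens))
    print(" ".join(tags))
    print(f"  {len(triplets)} triplet(s), overlap category: {sorted(cats)}")

# The SEO sentence shares one subject across two facts; the EPO sentence
# links the same (subject, object) pair under two relations. Both patterns
# are what plain once-per-token relation labeling cannot represent.
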