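"""Strict-match precision/recall/F1 over triplets, with overlap breakdown.

A predicted triplet is correct only under the strict criterion: subject span
boundaries AND subject entity type, relation name, and object span
boundaries must all equal a gold triplet's.  Objects carry no predicted type
(the binary taggers are untyped), so object correctness is boundaries plus
relation.  Duplicate predictions count once, and each gold triplet can be
matched at most once.

``breakdown_by_overlap`` assigns every sentence to each overlap category its
gold triplets exhibit (NORMAL / SEO / EPO, non-exclusive) and scores the
categories independently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .schema import EPO, NORMAL, SEO, Triplet, classify_overlap

__all__ = ["MatchCounts", "match_triplets", "prf", "breakdown_by_overlap",
           "error_listing"]


def _pred_key(t: Triplet) -> tuple:
    # object type intentionally excluded: taggers predict no object type
    return (t.subject.start, t.subject.end, t.subject.type,
            t.relation, t.object.start, t.object.end)


@dataclass
class MatchCounts:
    """True-positive / predicted / gold tallies for one evaluation slice."""

    true_positive: int = 0
    predicted_total: int = 0
    gold_total: int = 0

    def __post_init__(self):
        if min(self.true_positive, self.predicted_total, self.gold_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.true_positive > min(self.predicted_total, self.gold_total):
            raise ValueError("true positives exceed predicted or gold totals")

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.true_positive += other.true_positive
        self.predicted_total += other.predicted_total
        self.gold_total += other.gold_total
        return self


def match_triplets(pred: list[Triplet], gold: list[Triplet]) -> MatchCounts:
    """Strict matching for one sentence; both lists are deduplicated."""
    pred_keys = {_pred_key(t) for t in pred}
    gold_keys = {_pred_key(t) for t in gold}
    tp = len(pred_keys & gold_keys)
    return MatchCounts(true_positive=tp, predicted_total=len(pred_keys),
                       gold_total=len(gold_keys))


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and F1; zero denominators yield 0 by convention."""
    p = counts.true_positive / counts.predicted_total if counts.predicted_total else 0.0
    r = counts.true_positive / counts.gold_total if counts.gold_total else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def corpus_counts(pred_per_sentence: list[list[Triplet]],
                  gold_per_sentence: list[list[Triplet]]) -> MatchCounts:
    """Aggregate strict-match counts over aligned sentence lists."""
    if len(pred_per_sentence) != len(gold_per_sentence):
        raise ValueError("prediction/gold sentence counts differ")
    total = MatchCounts()
    for pred, gold in zip(pred_per_sentence, gold_per_sentence):
        total += match_triplets(pred, gold)
    return total


def breakdown_by_overlap(pred_per_sentence: list[list[Triplet]],
                         gold_per_sentence: list[list[Triplet]],
                         ) -> dict[str, MatchCounts]:
    """Per-category counts; a sentence scores in every category it exhibits."""
    if len(pred_per_sentence) != len(gold_per_sentence):
        raise ValueError("prediction/gold sentence counts differ")
    out = {NORMAL: MatchCounts(), SEO: MatchCounts(), EPO: MatchCounts()}
    for pred, gold in zip(pred_per_sentence, gold_per_sentence):
        if not gold:
            continue
        counts = match_triplets(pred, gold)
        for cat in classify_overlap(gold):
            out[cat] += counts
    return out


def error_listing(pred: list[Triplet], gold: list[Triplet]) -> dict[str, list[Triplet]]:
    """False positives and false negatives of one sentence, for inspection."""
    pred_keys = {_pred_key(t): t for t in pred}
    gold_keys = {_pred_key(t): t for t in gold}
    return {
        "false_positives": [t for k, t in sorted(pred_keys.items())
                            if k not in gold_keys],
        "false_negatives": [t for k, t in sorted(gold_keys.items())
                            if k not in pred_keys],
    }
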