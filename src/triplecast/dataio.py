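"""Dataset readers/writers: a JSONL annotation dialect and CoNLL tag export.

One JSON object per line::

    {"text": ["kiwi", "fruit", ...] or "raw string",
     "entities": [{"start": 0, "end": 2, "type": "FRU"}, ...],
     "triplets": [{"subject": [0, 2], "relation": "origin",
                   "object": [5, 6]}, ...]}

Offsets are 0-based half-open token indices.  A raw string ``text`` is
tokenized per character (the annotation convention for Chinese); a list is
taken as pre-tokenized.  Every record is validated on read and failures
name the offending line.  Triplet spans must appear in ``entities``; a
triplet object absent from ``entities`` is accepted as untyped.
"""

from __future__ import annotations

import json
from pathlib import Path

from .corpus import CorpusExample
from .schema import Span, Triplet, UNTYPED, spans_to_tags

__all__ = ["ParseError", "read_jsonl", "write_jsonl", "export_conll",
           "import_conll"]


class ParseError(ValueError):
    """Malformed dataset file; the message names the line number."""


def _tokens_of(text) -> list[str]:
    if isinstance(text, str):
        return list(text)  # per-character tokenization
    if isinstance(text, list) and all(isinstance(t, str) for t in text):
        return text
    raise ValueError("text must be a string or a list of token strings")


def _record_to_example(rec: dict) -> CorpusExample:
    tokens = _tokens_of(rec.get("text"))
    n = len(tokens)
    spans = []
    typed: dict[tuple[int, int], str] = {}
    for ent in rec.get("entities", []):
        s, e, t = int(ent["start"]), int(ent["end"]), str(ent["type"])
        if not (0 <= s < e <= n):
            raise ValueError(f"entity offsets [{s}, {e}) outside text of length {n}")
        sp = Span(s, e, t)
        spans.append(sp)
        typed[(s, e)] = t
    triplets = []
    for tr in rec.get("triplets", []):
        ss, se = (int(v) for v in tr["subject"])
        os_, oe = (int(v) for v in tr["object"])
        rel = str(tr["relation"])
        if not (0 <= ss < se <= n and 0 <= os_ < oe <= n):
            raise ValueError(f"triplet offsets outside text of length {n}")
        if (ss, se) not in typed:
            raise ValueError(f"triplet subject [{ss}, {se}) not in entities")
        subj = Span(ss, se, typed[(ss, se)])
        obj = Span(os_, oe, typed.get((os_, oe), UNTYPED))
        triplets.append(Triplet(subj, rel, obj))
    return CorpusExample(tokens=tokens, spans=spans,
                         tags=spans_to_tags(spans, n), triplets=triplets)


def read_jsonl(path: str | Path) -> list[CorpusExample]:
    """Read and validate a JSONL corpus; errors name the offending line."""
    examples = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                examples.append(_record_to_example(rec))
            except (ValueError, KeyError, TypeError) as err:
                raise ParseError(f"{path}, line {lineno}: {err}") from err
    return examples


def write_jsonl(corpus: list[CorpusExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in corpus:
            rec = {
                "text": ex.tokens,
                "entities": [{"start": sp.start, "end": sp.end, "type": sp.type}
                             for sp in ex.spans],
                "triplets": [{"subject": [tr.subject.start, tr.subject.end],
                              "relation": tr.relation,
                              "object": [tr.object.start, tr.object.end]}
                             for tr in ex.triplets],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def export_conll(corpus: list[CorpusExample], path: str | Path,
                 warn=None) -> None:
    """Write ``token TAB tag`` lines, blank line between sentences.

    The format carries tags only; triplets are dropped (``warn`` is called
    once with a message if any example has them).
    """
    if warn is not None and any(ex.triplets for ex in corpus):
        warn("CoNLL export keeps tags only; triplet annotations are dropped")
    with open(path, "w", encoding="utf-8") as fh:
        for ex in corpus:
            for tok, tag in zip(ex.tokens, ex.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def import_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read ``token TAB tag`` sentences back (tags only, no triplets)."""
    sents: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                if toks:
                    sents.append((toks, tags))
                    toks, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 'token<TAB>tag'")
            toks.append(parts[0])
            tags.append(parts[1])
    if toks:
        sents.append((toks, tags))
    return sents
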