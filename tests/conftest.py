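import numpy as np
import pytest

from triplecast.corpus import CorpusConfig, CorpusExample, generate_corpus
from triplecast.schema import Span, Triplet, spans_to_tags


@pytest.fixture(scope="session")
def small_corpus():
    """120 deterministic sentences with the default overlap mix."""
    return generate_corpus(CorpusConfig(n_sentences=120, seed=42))


def make_example(tokens, spans, triplets):
    return CorpusExample(tokens=tokens, spans=spans,
                         tags=spans_to_tags(spans, len(tokens)),
                         triplets=triplets)


@pytest.fixture(scope="session")
def fruit_sentences():
    """Three hand-annotated sentences mirroring the canonical
    NORMAL / SEO / EPO fruit-nutrition examples (five triplets total)."""
    # "Kiwifruit belongs-to Actinidiaceae"
    normal = make_example(
        ["Kiwifruit", "belongs", "to", "Actinidiaceae"],
        [Span(0, 1, "FRU"), Span(3, 4, "SEC")],
        [Triplet(Span(0, 1, "FRU"), "belong", Span(3, 4, "SEC"))])
    # "Kiwifruit is rich in vitamin-C , grape-acid"
    seo_sub = Span(0, 1, "FRU")
    seo = make_example(
        ["Kiwifruit", "is", "rich", "in", "vitamin", "C", ",", "grape", "acid"],
        [seo_sub, Span(4, 6, "NUT"), Span(7, 9, "NUT")],
        [Triplet(seo_sub, "rich_in", Span(4, 6, "NUT")),
         Triplet(seo_sub, "rich_in", Span(7, 9, "NUT"))])
    # "Kiwifruit is mainly processed and produced in Shaanxi"
    epo_sub = Span(0, 1, "FRU")
    epo_obj = Span(7, 8, "LOC")
    epo = make_example(
        ["Kiwifruit", "is", "mainly", "processed", "and", "produced", "in",
         "Shaanxi"],
        [epo_sub, epo_obj],
        [Triplet(epo_sub, "origin", epo_obj),
         Triplet(epo_sub, "process", epo_obj)])
    return [normal, seo, epo]
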