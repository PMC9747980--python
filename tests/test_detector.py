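import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triplecast.autodiff import Tensor
from triplecast.crf import LabelEmbeddingTable, SubjectCandidate
from triplecast.detector import (DetectionConfig, ObjectProbabilities,
                                 RelationTaggerParams, assemble_triplets,
                                 match_spans, subject_label_vector,
                                 tag_objects, tag_objects_all_relations)
from triplecast.schema import (EntityTypeSet, RelationSchema, Span,
                               build_tagset, UNTYPED)

TAGSET = build_tagset(EntityTypeSet(["FRU", "LOC"]))
RELS = RelationSchema(["origin", "process"])


def fru_subject(start=0, length=3):
    names = (["B-FRU"] if length == 1
             else ["B-FRU"] + ["I-FRU"] * (length - 2) + ["E-FRU"])
    return SubjectCandidate(span=Span(start, start + length, "FRU"),
                            tag_ids=tuple(TAGSET.index_of(t) for t in names))


class TestSubjectLabelVector:
    def test_three_token_subject_sums_b_i_e_rows(self):
        table = LabelEmbeddingTable(n_tags=len(TAGSET), dim=6)
        rows = table.rows().data
        got = subject_label_vector(fru_subject(length=3), table).data
        expected = (rows[TAGSET.index_of("B-FRU")]
                    + rows[TAGSET.index_of("I-FRU")]
                    + rows[TAGSET.index_of("E-FRU")])
        np.testing.assert_allclose(got, expected)

    def test_single_token_subject_is_its_b_row(self):
        table = LabelEmbeddingTable(n_tags=len(TAGSET), dim=6)
        got = subject_label_vector(fru_subject(length=1), table).data
        np.testing.assert_allclose(
            got, table.rows().data[TAGSET.index_of("B-FRU")])

    def test_zeroed_table_gives_zero_vector(self):
        table = LabelEmbeddingTable(n_tags=len(TAGSET), dim=6)
        table.base.data[...] = 0.0
        table.b_l.data[...] = 0.0
        np.testing.assert_array_equal(
            subject_label_vector(fru_subject(), table).data, np.zeros(6))


class TestTagObjects:
    def test_zero_parameters_give_half_everywhere(self):
        params = RelationTaggerParams(relations=RELS, dim=4)
        for t in (params.W_start, params.b_start, params.W_end, params.b_end):
            t.data[...] = 0.0
        x = Tensor(np.random.default_rng(0).normal(size=(5, 4)))
        probs = tag_objects(x, None, None, params, "origin")
        np.testing.assert_allclose(probs.p_start, 0.5)
        np.testing.assert_allclose(probs.p_end, 0.5)

    def test_probabilities_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        params = RelationTaggerParams(relations=RELS, dim=4,
                                      rng=np.random.default_rng(1))
        x = Tensor(rng.normal(size=(7, 4)) * 10)
        ps, pe = tag_objects_all_relations(x, None, None, params)
        assert ((ps.data > 0) & (ps.data < 1)).all()
        assert ((pe.data > 0) & (pe.data < 1)).all()

    def test_hand_computed_single_token_case(self):
        params = RelationTaggerParams(relations=RelationSchema(["r"]), dim=3)
        w = np.array([[0.5, -1.0, 2.0]])
        params.W_start.data = w.copy()
        params.b_start.data = np.array([0.25])
        x = np.array([[1.0, 2.0, 3.0]])
        l_sub = np.array([0.1, 0.1, 0.1])
        v = np.array([[0.0, 0.5, -0.5]])
        probs = tag_objects(Tensor(x), Tensor(l_sub), Tensor(v), params, "r")
        z = w[0] @ (x[0] + l_sub + v[0]) + 0.25
        assert probs.p_start[0] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        params = RelationTaggerParams(relations=RELS, dim=4)
        with pytest.raises(ValueError):
            tag_objects_all_relations(Tensor(np.zeros((3, 4))), None,
                                      Tensor(np.zeros((2, 4))), params)

    def test_per_position_output_ignores_position_permutation(self):
        # with fixed fused inputs, swapping two rows swaps the outputs
        params = RelationTaggerParams(relations=RELS, dim=4,
                                      rng=np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(6, 4))
        ps1, _ = tag_objects_all_relations(Tensor(x), None, None, params)
        perm = np.array([5, 4, 3, 2, 1, 0])
        ps2, _ = tag_objects_all_relations(Tensor(x[perm]), None, None, params)
        np.testing.assert_allclose(ps1.data[perm], ps2.data)


def probs_from_flags(starts, ends, n=10, hi=0.95, lo=0.05):
    p_s = np.full(n, lo)
    p_e = np.full(n, lo)
    p_s[list(starts)] = hi
    p_e[list(ends)] = hi
    return ObjectProbabilities(p_start=p_s, p_end=p_e)


class TestMatchSpans:
    CFG = DetectionConfig(threshold=0.86)

    def test_start_pairs_with_nearest_end_at_or_after(self):
        spans = match_spans(probs_from_flags({2}, {4}), self.CFG, None)
        assert spans == [Span(2, 5, UNTYPED)]

    def test_same_position_start_and_end_is_length_one(self):
        spans = match_spans(probs_from_flags({9}, {9}), self.CFG, None)
        assert spans == [Span(9, 10, UNTYPED)]

    def test_no_flags_no_spans(self):
        assert match_spans(probs_from_flags(set(), set()), self.CFG, None) == []

    def test_unmatched_start_dropped(self):
        spans = match_spans(probs_from_flags({2, 6}, {3}), self.CFG, None)
        assert spans == [Span(2, 4, UNTYPED)]

    def test_ends_consumed_left_to_right(self):
        spans = match_spans(probs_from_flags({0, 2}, {1, 4}), self.CFG, None)
        assert spans == [Span(0, 2, UNTYPED), Span(2, 5, UNTYPED)]

    def test_type_attached_when_boundaries_coincide(self):
        spans = match_spans(probs_from_flags({2}, {4}), self.CFG,
                            {(2, 5): "LOC"})
        assert spans == [Span(2, 5, "LOC")]

    @given(st.data())
    @settings(max_examples=80, derandomize=True)
    def test_span_count_monotone_in_threshold(self, data):
        n = data.draw(st.integers(1, 12))
        p_s = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
        p_e = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
        probs = ObjectProbabilities(p_start=p_s, p_end=p_e)
        counts = [len(match_spans(probs, DetectionConfig(threshold=t), None))
                  for t in (0.5, 0.7, 0.86, 0.95)]
        assert counts == sorted(counts, reverse=True)


class TestAssembleTriplets:
    def test_epo_pair_yields_two_triplets(self):
        subj = fru_subject()
        obj = [Span(9, 10, UNTYPED)]
        trips = assemble_triplets([(subj, "process", obj), (subj, "origin", obj)])
        assert len(trips) == 2
        assert {t.relation for t in trips} == {"origin", "process"}
        assert all(t.object.start == 9 for t in trips)

    def test_no_subjects_no_triplets(self):
        assert assemble_triplets([]) == []

    def test_one_subject_two_objects_is_two_seo_triplets(self):
        subj = fru_subject()
        spans = [Span(5, 6, UNTYPED), Span(8, 9, UNTYPED)]
        trips = assemble_triplets([(subj, "origin", spans)])
        assert len(trips) == 2

    def test_exact_duplicates_collapse(self):
        subj = fru_subject()
        obj = [Span(5, 6, UNTYPED)]
        trips = assemble_triplets([(subj, "origin", obj), (subj, "origin", obj)])
        assert len(trips) == 1
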