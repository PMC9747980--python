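"""CRF scoring, decoding and likelihood against brute-force enumeration."""

from itertools import product

import numpy as np
import pytest

from triplecast.autodiff import Tensor
from triplecast.crf import (CrfParams, LabelEmbeddingTable, candidate_subjects,
                            crf_nll, crf_score, lookup_char_labels,
                            viterbi_decode)
from triplecast.schema import EntityTypeSet, Span, build_tagset


def random_crf(rng, n_tags, dim=4):
    params = CrfParams(n_tags=n_tags, dim=dim,
                       rng=np.random.default_rng(int(rng.integers(2**31))))
    params.transitions.data = rng.normal(size=(n_tags, n_tags))
    params.start.data = rng.normal(size=n_tags)
    params.stop.data = rng.normal(size=n_tags)
    return params


def enumerate_scores(emissions, params):
    n, k = emissions.shape
    return {seq: crf_score(emissions, params, seq)
            for seq in product(range(k), repeat=n)}


class TestCrfScore:
    def test_single_token_is_emission_plus_boundaries(self):
        rng = np.random.default_rng(0)
        params = random_crf(rng, 3)
        em = rng.normal(size=(1, 3))
        assert crf_score(em, params, [2]) == pytest.approx(
            em[0, 2] + params.start.data[2] + params.stop.data[2])

    def test_all_zero_parameters_scores_zero(self):
        params = CrfParams(n_tags=4, dim=2)
        for t in (params.transitions, params.start, params.stop):
            t.data[...] = 0.0
        em = np.zeros((3, 4))
        for seq in product(range(4), repeat=3):
            assert crf_score(em, params, seq) == 0.0

    def test_matches_hand_summed_path(self):
        rng = np.random.default_rng(1)
        params = random_crf(rng, 4)
        em = rng.normal(size=(3, 4))
        tags = [1, 3, 0]
        expected = (params.start.data[1] + em[0, 1]
                    + params.transitions.data[1, 3] + em[1, 3]
                    + params.transitions.data[3, 0] + em[2, 0]
                    + params.stop.data[0])
        assert crf_score(em, params, tags) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        params = CrfParams(n_tags=3, dim=2)
        with pytest.raises(ValueError):
            crf_score(np.zeros((2, 3)), params, [0, 1, 2])


class TestViterbi:
    def test_single_position_is_argmax_row(self):
        rng = np.random.default_rng(2)
        params = random_crf(rng, 5)
        params.start.data[...] = 0.0
        params.stop.data[...] = 0.0
        em = rng.normal(size=(1, 5))
        assert viterbi_decode(em, params) == [int(np.argmax(em[0]))]

    def test_zero_transitions_reduce_to_per_position_argmax(self):
        rng = np.random.default_rng(3)
        params = CrfParams(n_tags=4, dim=2)
        for t in (params.transitions, params.start, params.stop):
            t.data[...] = 0.0
        em = rng.normal(size=(6, 4))
        assert viterbi_decode(em, params) == list(np.argmax(em, axis=1))

    def test_ties_break_to_lowest_tag_id(self):
        params = CrfParams(n_tags=3, dim=2)
        for t in (params.transitions, params.start, params.stop):
            t.data[...] = 0.0
        assert viterbi_decode(np.zeros((4, 3)), params) == [0, 0, 0, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            viterbi_decode(np.zeros((0, 3)), CrfParams(n_tags=3, dim=2))

    @pytest.mark.parametrize("trial_block", range(4))
    def test_matches_exhaustive_enumeration(self, trial_block):
        rng = np.random.default_rng(100 + trial_block)
        for _ in range(60):
            n = int(rng.integers(1, 7))
            k = int(rng.integers(2, 6))
            params = random_crf(rng, k)
            em = rng.normal(size=(n, k)) * 2
            scores = enumerate_scores(em, params)
            best = max(scores.values())
            vit = tuple(viterbi_decode(em, params))
            assert scores[vit] == pytest.approx(best, abs=1e-9)


class TestCrfNll:
    def test_single_tag_alphabet_has_zero_loss(self):
        params = CrfParams(n_tags=1, dim=2)
        em = np.random.default_rng(0).normal(size=(4, 1))
        assert crf_nll(em, params, [0, 0, 0, 0]).item() == pytest.approx(0.0)

    @pytest.mark.parametrize("trial_block", range(4))
    def test_matches_enumerated_partition(self, trial_block):
        rng = np.random.default_rng(200 + trial_block)
        for _ in range(60):
            n = int(rng.integers(1, 7))
            k = int(rng.integers(2, 6))
            params = random_crf(rng, k)
            em = rng.normal(size=(n, k)) * 2
            scores = enumerate_scores(em, params)
            log_z = np.logaddexp.reduce(np.array(list(scores.values())))
            gold = tuple(int(rng.integers(k)) for _ in range(n))
            nll = crf_nll(em, params, gold).item()
            assert nll == pytest.approx(log_z - scores[gold], abs=1e-6)
            assert nll >= -1e-12  # log-sum-exp dominates any single path

    def test_loss_vanishes_when_gold_dominates(self):
        # temperature -> infinity: scaling emissions of the Viterbi path
        rng = np.random.default_rng(5)
        params = random_crf(rng, 3)
        big = rng.normal(size=(4, 3)) * 200.0
        gold = viterbi_decode(big, params)
        assert crf_nll(big, params, gold).item() == pytest.approx(0.0, abs=1e-6)

    def test_invalid_gold_tag_rejected(self):
        params = CrfParams(n_tags=3, dim=2)
        with pytest.raises(ValueError):
            crf_nll(np.zeros((2, 3)), params, [0, 7])


SIX = build_tagset(EntityTypeSet(["FRU", "SEC", "NUT", "PER", "SYM", "LOC"]))


class TestLabelLookup:
    def test_identical_tags_yield_identical_vectors(self):
        table = LabelEmbeddingTable(n_tags=len(SIX), dim=8)
        ids = np.array([3, 0, 3, 5])
        v = lookup_char_labels(ids, table).data
        np.testing.assert_array_equal(v[0], v[2])
        assert v.shape == (4, 8)

    def test_lookup_applies_affine_map(self):
        table = LabelEmbeddingTable(n_tags=4, dim=3)
        expected = table.base.data @ table.W_l.data + table.b_l.data
        v = lookup_char_labels(np.arange(4), table).data
        np.testing.assert_allclose(v, expected)


class TestCandidateSubjects:
    def test_three_token_fruit_entity(self):
        tags = ["B-FRU", "I-FRU", "E-FRU", "O", "O"]
        cands = candidate_subjects(tags, SIX)
        assert len(cands) == 1
        assert cands[0].span == Span(0, 3, "FRU")
        assert cands[0].tag_ids == tuple(SIX.index_of(t)
                                         for t in ("B-FRU", "I-FRU", "E-FRU"))

    def test_all_outside_yields_nothing(self):
        assert candidate_subjects(["O", "O", "O"], SIX) == []
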