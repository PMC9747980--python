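import math

import numpy as np
import pytest

from triplecast.autodiff import Tensor
from triplecast.corpus import CorpusConfig, generate_corpus, split_corpus
from triplecast.encoder import build_vocab
from triplecast.training import (Adam, ModelState, TrainConfig,
                                 binary_tagger_loss, evaluate_model,
                                 infer_schema, load_checkpoint, predict,
                                 save_checkpoint, total_loss, train)


@pytest.fixture(scope="module")
def tiny_corpus():
    return generate_corpus(CorpusConfig(n_sentences=10, seed=21))


@pytest.fixture(scope="module")
def tiny_model(tiny_corpus):
    e, r = infer_schema(tiny_corpus)
    cfg = TrainConfig(dim=6, seed=0, dropout=0.0)
    return ModelState(e, r, build_vocab(tiny_corpus), cfg)


class TestBinaryTaggerLoss:
    def test_correct_confident_prediction_costs_nothing(self):
        p = Tensor(np.array([1.0, 0.0]))
        y = np.array([1.0, 0.0])
        loss = binary_tagger_loss(p, p, y, y)
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_half_probability_costs_ln2_per_element(self):
        p = Tensor(np.full(4, 0.5))
        y = np.ones(4)
        loss = binary_tagger_loss(p, p, y, y)
        assert loss.item() == pytest.approx(8 * math.log(2), abs=1e-9)

    def test_matches_elementwise_hand_computation(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0.05, 0.95, size=5)
        pe = rng.uniform(0.05, 0.95, size=5)
        ys = (rng.random(5) > 0.5).astype(float)
        ye = (rng.random(5) > 0.5).astype(float)
        expected = -(ys * np.log(ps) + (1 - ys) * np.log(1 - ps)).sum() \
            - (ye * np.log(pe) + (1 - ye) * np.log(1 - pe)).sum()
        got = binary_tagger_loss(Tensor(ps), Tensor(pe), ys, ye).item()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_tagger_loss(Tensor(np.zeros(3)), Tensor(np.zeros(3)),
                               np.zeros(4), np.zeros(3))

    def test_non_binary_indicators_rejected(self):
        with pytest.raises(ValueError):
            binary_tagger_loss(Tensor(np.full(2, 0.5)), Tensor(np.full(2, 0.5)),
                               np.array([0.5, 1.0]), np.zeros(2))

    def test_extreme_probabilities_stay_finite(self):
        p = Tensor(np.array([0.0, 1.0]))
        y = np.array([1.0, 0.0])  # maximally wrong
        loss = binary_tagger_loss(p, p, y, y).item()
        assert np.isfinite(loss) and loss > 10


class TestTotalLoss:
    def test_gradients_match_finite_differences(self, tiny_corpus, tiny_model):
        model = tiny_model
        batch = tiny_corpus[:3]
        model.zero_grad()
        total_loss(batch, model).backward()
        rng = np.random.default_rng(1)
        checked = 0
        for name, p in model.parameter_items():
            flat = p.data.reshape(-1)
            grad = p.grad.reshape(-1) if p.grad is not None else \
                np.zeros(flat.size)
            for k in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                orig = flat[k]
                flat[k] = orig + 1e-5
                fp = total_loss(batch, model).item()
                flat[k] = orig - 1e-5
                fm = total_loss(batch, model).item()
                flat[k] = orig
                num = (fp - fm) / 2e-5
                assert grad[k] == pytest.approx(num, abs=1e-4, rel=1e-4), name
                checked += 1
        assert checked > 40

    def test_removing_a_relations_gold_objects_reduces_only_its_term(
            self, tiny_corpus, tiny_model):
        import copy
        base = total_loss(tiny_corpus[:4], tiny_model).item()
        stripped = copy.deepcopy(tiny_corpus[:4])
        dropped = None
        for ex in stripped:
            if ex.triplets:
                dropped = ex.triplets.pop()
                break
        assert dropped is not None
        after = total_loss(stripped, tiny_model).item()
        # near-uniform initial probabilities: removing a positive target
        # swaps a ~log 2 "predict 1" term for a ~log 2 "predict 0" term of
        # similar size, so the change is bounded by a few nats
        assert after != base
        assert abs(after - base) < 2.0

    def test_empty_batch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            total_loss([], tiny_model)


class TestPredict:
    def test_zeroed_taggers_emit_nothing_at_default_threshold(
            self, tiny_corpus, tiny_model):
        # sigmoid(0) = 0.5 < 0.86, so no start/end flags anywhere
        model = tiny_model
        snap = model.snapshot()
        for t in (model.tagger.W_start, model.tagger.b_start,
                  model.tagger.W_end, model.tagger.b_end):
            t.data[...] = 0.0
        try:
            for ex in tiny_corpus[:5]:
                assert predict(model, ex.tokens) == []
        finally:
            model.restore(snap)

    def test_empty_sentence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            predict(tiny_model, [])

    def test_sentence_with_no_entities_yields_nothing(self, tiny_corpus):
        cfg = TrainConfig(dim=6, seed=0, epochs=2, dropout=0.0)
        model = train(tiny_corpus, cfg, val=[])
        # filler-only sentence: the CRF has no entity evidence
        out = predict(model, ["w0", "w1", "w0"])
        assert out == [] or all(t.subject.type for t in out)


class TestTrainLoop:
    def test_one_epoch_smoke_run_finishes_with_finite_loss(self, tiny_corpus):
        log = []
        cfg = TrainConfig(dim=6, seed=0, epochs=1)
        train(tiny_corpus, cfg, val=[], log=log)
        assert len(log) == 1
        assert np.isfinite(log[0]["loss"])

    def test_same_seed_reproduces_epoch_one_loss(self, tiny_corpus):
        cfg = TrainConfig(dim=6, seed=5, epochs=1)
        log_a, log_b = [], []
        train(tiny_corpus, cfg, val=[], log=log_a)
        train(tiny_corpus, cfg, val=[], log=log_b)
        assert log_a[0]["loss"] == log_b[0]["loss"]

    def test_loss_decreases_over_first_five_epochs(self):
        # median first-vs-fifth epoch loss over three seeds
        corpus = generate_corpus(CorpusConfig(n_sentences=60, seed=31))
        drops = []
        for seed in (0, 1, 2):
            log = []
            train(corpus, TrainConfig(dim=16, seed=seed, epochs=5),
                  val=[], log=log)
            drops.append(log[0]["loss"] - log[4]["loss"])
        assert np.median(drops) > 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        corpus = generate_corpus(CorpusConfig(n_sentences=80, seed=13))
        tr, va, te = split_corpus(corpus, seed=13)
        model = train(tr, TrainConfig(dim=24, seed=3, epochs=6), val=va)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path))
        assert loaded.vocab.tokens == model.vocab.tokens
        assert list(loaded.relations) == list(model.relations)
        for ex in te:
            assert predict(loaded, ex.tokens) == predict(model, ex.tokens)
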