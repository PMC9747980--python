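"""Joint training of encoder, CRF, label table and relation taggers.

The total loss is the unit-weighted sum of the two extraction sections: the
CRF negative log-likelihood of the gold BIOE sequence (subject section) and
binary cross-entropy over the start/end heads of every relation for every
candidate subject (relation-object section).  Training uses teacher forcing:
gold tags supply the character-label vectors and gold entity spans supply
the candidate subjects.  Gold spans that are never subjects still enter the
tagger batch with all-zero targets, so at inference the taggers have seen —
and learned to reject — non-subject candidates the CRF will surface.

Optimization is Adam on minibatches; the best parameters by validation
strict F1 are kept.  All randomness (shuffling, dropout, initialization)
descends from the single config seed, so runs are reproducible on fixed
hardware.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, where
from .corpus import CorpusExample, split_corpus
from .crf import (CrfParams, LabelEmbeddingTable, SubjectCandidate,
                  candidate_subjects, crf_nll_batch, viterbi_decode)
from .detector import (DetectionConfig, ObjectProbabilities,
                       RelationTaggerParams, assemble_triplets, match_spans)
from .encoder import Encoder, Vocab, build_vocab
from .evaluation import corpus_counts, prf
from .schema import (EntityTypeSet, RelationSchema, Span, TagSet, Triplet,
                     build_tagset)

__all__ = ["TrainConfig", "ModelState", "train", "predict",
           "binary_tagger_loss", "total_loss", "Adam",
           "save_checkpoint", "load_checkpoint"]

_EPS = 1e-7  # probability clamp inside the loss


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_len: int = 100
    dim: int = 64
    dropout: float = 0.2
    optimizer: str = "adam"
    learning_rate: float = 1e-2
    epochs: int = 50
    threshold: float = 0.86
    seed: int = 0
    use_subject_label: bool = True
    use_char_label: bool = True
    use_context: bool = True
    patience: int | None = None  # stop after this many epochs w/o val gain

    def __post_init__(self):
        for name in ("batch_size", "max_len", "dim", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class ModelState:
    """Everything needed to run the cascade: schema, vocab and parameters."""

    def __init__(self, entity_types: EntityTypeSet, relations: RelationSchema,
                 vocab: Vocab, config: TrainConfig):
        self.entity_types = entity_types
        self.relations = relations
        self.tagset: TagSet = build_tagset(entity_types)
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(len(vocab), dim=config.dim,
                               max_len=config.max_len, dropout=config.dropout,
                               use_context=config.use_context, rng=rng)
        self.crf = CrfParams(n_tags=len(self.tagset), dim=config.dim, rng=rng)
        self.labels = LabelEmbeddingTable(n_tags=len(self.tagset),
                                          dim=config.dim, rng=rng)
        self.tagger = RelationTaggerParams(relations=relations,
                                           dim=config.dim, rng=rng)
        self.detection = DetectionConfig(threshold=config.threshold)

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return (self.encoder.parameter_items() + self.crf.parameter_items()
                + self.labels.parameter_items() + self.tagger.parameter_items())

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.parameter_items()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameter_items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in self.parameter_items():
            v.data[...] = snap[k]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _clamp_probs(p: Tensor) -> Tensor:
    lo = np.full(p.shape, _EPS)
    hi = np.full(p.shape, 1.0 - _EPS)
    p = where(p.data < _EPS, Tensor(lo), p)
    return where(p.data > 1.0 - _EPS, Tensor(hi), p)


def binary_tagger_loss(p_start: Tensor, p_end: Tensor,
                       y_start: np.ndarray, y_end: np.ndarray,
                       mask: np.ndarray | None = None) -> Tensor:
    """Binary cross-entropy summed over positions, heads, subjects, relations.

    ``p_*`` are probability tensors of any matching shape, ``y_*`` are 0/1
    indicator arrays; ``mask`` (broadcastable) excludes padded positions.
    Probabilities are clamped to ``[1e-7, 1 - 1e-7]``, keeping the loss
    finite without moving its minimizers.
    """
    from .autodiff import log

    if p_start.shape != y_start.shape or p_end.shape != y_end.shape:
        raise ValueError("probability/indicator shape mismatch")
    total = Tensor(0.0)
    for p, y in ((p_start, y_start), (p_end, y_end)):
        y = np.asarray(y, dtype=float)
        if ((y != 0) & (y != 1)).any():
            raise ValueError("gold indicators must be 0 or 1")
        p = _clamp_probs(p)
        ll = y * log(p) + (1.0 - y) * log(1.0 - p)
        if mask is not None:
            ll = ll * mask
        total = total + -(ll.sum())
    return total


# -- batch assembly -------------------------------------------------------

@dataclass
class _Batch:
    ids: np.ndarray            # (B, T)
    mask: np.ndarray           # (B, T)
    tag_ids: np.ndarray        # (B, T) gold, O-padded
    subj_sentence: np.ndarray  # (S,) sentence index of each candidate subject
    subj_tag_counts: np.ndarray  # (S, K) tag multiplicity -> label-vector sum
    y_start: np.ndarray        # (S, T, R)
    y_end: np.ndarray          # (S, T, R)


def _make_batch(examples: list[CorpusExample], vocab: Vocab, tagset: TagSet,
                relations: RelationSchema, max_len: int) -> _Batch:
    B = len(examples)
    T = max(min(len(ex.tokens), max_len) for ex in examples)
    K, R = len(tagset), len(relations)
    ids = np.zeros((B, T), dtype=np.intp)
    mask = np.zeros((B, T), dtype=bool)
    tag_ids = np.full((B, T), tagset.outside_id, dtype=np.intp)

    subj_sentence: list[int] = []
    counts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    ye: list[np.ndarray] = []
    for b, ex in enumerate(examples):
        n = min(len(ex.tokens), max_len)
        ids[b, :n] = vocab.encode_tokens(ex.tokens[:n])
        mask[b, :n] = True
        tag_ids[b, :n] = [tagset.index_of(t) for t in ex.tags[:n]]

        by_subject: dict[Span, list] = {}
        for tr in ex.triplets:
            by_subject.setdefault(tr.subject, []).append(tr)
        # teacher forcing: every gold span is a candidate; non-subject spans
        # get all-zero targets (negative candidates)
        for sp in ex.spans:
            if sp.end > n:
                continue
            c = np.zeros(K)
            for i in sp.positions():
                c[tag_ids[b, i]] += 1
            y_s = np.zeros((T, R))
            y_e = np.zeros((T, R))
            for tr in by_subject.get(sp, []):
                if tr.object.end > n:
                    continue
                r = relations.index(tr.relation)
                y_s[tr.object.start, r] = 1.0
                y_e[tr.object.end - 1, r] = 1.0
            subj_sentence.append(b)
            counts.append(c)
            ys.append(y_s)
            ye.append(y_e)

    return _Batch(ids=ids, mask=mask, tag_ids=tag_ids,
                  subj_sentence=np.asarray(subj_sentence, dtype=np.intp),
                  subj_tag_counts=np.stack(counts) if counts else np.zeros((0, K)),
                  y_start=np.stack(ys) if ys else np.zeros((0, T, R)),
                  y_end=np.stack(ye) if ye else np.zeros((0, T, R)))


def total_loss(batch_examples: list[CorpusExample], model: ModelState,
               train_mode: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
    """Mean per-sentence loss: CRF NLL plus binary tagger cross-entropy."""
    if not batch_examples:
        raise ValueError("empty batch")
    from .autodiff import sigmoid

    cfg = model.config
    batch = _make_batch(batch_examples, model.vocab, model.tagset,
                        model.relations, cfg.max_len)
    B = batch.ids.shape[0]
    h = model.encoder.encode_ids(batch.ids, batch.mask,
                                 train=train_mode, rng=rng)
    emissions = model.crf.emissions(h)
    loss = crf_nll_batch(emissions, batch.tag_ids, batch.mask, model.crf).sum()

    if batch.subj_sentence.size:
        rows = model.labels.rows()
        fused = h[batch.subj_sentence]  # (S, T, d)
        if cfg.use_subject_label:
            l_sub = Tensor(batch.subj_tag_counts) @ rows  # (S, d)
            fused = fused + l_sub.reshape(-1, 1, cfg.dim)
        if cfg.use_char_label:
            v = rows[batch.tag_ids]  # (B, T, d), teacher-forced gold tags
            fused = fused + v[batch.subj_sentence]
        p_start = sigmoid(fused @ model.tagger.W_start.T + model.tagger.b_start)
        p_end = sigmoid(fused @ model.tagger.W_end.T + model.tagger.b_end)
        m = batch.mask[batch.subj_sentence][:, :, None]
        loss = loss + binary_tagger_loss(p_start, p_end,
                                         batch.y_start, batch.y_end, mask=m)
    return loss / float(B)


# -- inference ------------------------------------------------------------

def predict(model: ModelState, tokens: list[str],
            threshold: float | None = None) -> list[Triplet]:
    """Run the full cascade on one sentence.

    Encode, Viterbi-decode the BIOE tags, extract candidate subjects, then
    for every subject and every relation score start/end positions and
    decode object spans by nearest-pair matching.  Character-label vectors
    come from the *predicted* tags at inference.
    """
    if not tokens:
        raise ValueError("cannot predict on an empty sentence")
    cfg = model.config
    det = DetectionConfig(threshold=cfg.threshold if threshold is None
                          else threshold)
    enc = model.encoder.encode(tokens, model.vocab, train=False)
    h = enc.vectors.data  # (n, d); inference is pure numpy
    emissions = h @ model.crf.W_emit.data + model.crf.b_emit.data
    tag_id_path = viterbi_decode(emissions, model.crf)
    tags = [model.tagset.tags[i] for i in tag_id_path]
    subjects = candidate_subjects(tags, model.tagset)
    if not subjects:
        return []

    rows = model.labels.rows().data
    n = h.shape[0]
    v = rows[tag_id_path] if cfg.use_char_label else np.zeros((n, cfg.dim))
    obj_type_map = {(s.span.start, s.span.end): s.span.type for s in subjects}

    detections: list[tuple[SubjectCandidate, str, list[Span]]] = []
    for subj in subjects:
        fused = h + v
        if cfg.use_subject_label:
            fused = fused + rows[list(subj.tag_ids)].sum(axis=0)
        z_start = fused @ model.tagger.W_start.data.T + model.tagger.b_start.data
        z_end = fused @ model.tagger.W_end.data.T + model.tagger.b_end.data
        p_start = 1.0 / (1.0 + np.exp(-z_start))
        p_end = 1.0 / (1.0 + np.exp(-z_end))
        for r_idx, rel in enumerate(model.relations):
            probs = ObjectProbabilities(p_start=p_start[:, r_idx],
                                        p_end=p_end[:, r_idx])
            spans = match_spans(probs, det, obj_type_map)
            if spans:
                detections.append((subj, rel, spans))
    return assemble_triplets(detections)


def evaluate_model(model: ModelState, examples: list[CorpusExample],
                   threshold: float | None = None) -> tuple[float, float, float]:
    """Strict-match P/R/F1 of the model over a sentence list."""
    preds = [predict(model, ex.tokens, threshold=threshold) for ex in examples]
    golds = [ex.triplets for ex in examples]
    return prf(corpus_counts(preds, golds))


# -- training loop --------------------------------------------------------

def train(corpus: list[CorpusExample], config: TrainConfig,
          entity_types: EntityTypeSet | None = None,
          relations: RelationSchema | None = None,
          val: list[CorpusExample] | None = None,
          log: list | None = None) -> ModelState:
    """Fit the cascade on ``corpus``; keep the best state by validation F1.

    When ``val`` is not given, ``corpus`` is shuffled under the config seed
    and split 7:2:1; the first part trains, the second validates (the final
    tenth is untouched, reserved for the caller's test split).  ``log``, if
    provided, receives one dict per epoch (epoch, loss, val P/R/F1).
    """
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    if entity_types is None or relations is None:
        e_auto, r_auto = infer_schema(corpus)
        entity_types = entity_types or e_auto
        relations = relations or r_auto
    if val is None:
        train_set, val_set, _ = split_corpus(corpus, seed=config.seed)
    else:
        train_set, val_set = corpus, val

    vocab = build_vocab(train_set)
    model = ModelState(entity_types, relations, vocab, config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    best_f1 = -1.0
    best_snap = model.snapshot()
    stale = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = [train_set[i] for i in idx]
            model.zero_grad()
            loss = total_loss(batch, model, train_mode=True, rng=rng)
            loss.backward()
            opt.step()
            model.encoder.params["emb"].data[0] = 0.0  # pad row stays zero
            epoch_loss += loss.item() * len(batch)
        epoch_loss /= len(train_set)

        p, r, f1 = evaluate_model(model, val_set) if val_set else (0.0, 0.0, 0.0)
        if log is not None:
            log.append({"epoch": epoch, "loss": epoch_loss,
                        "val_precision": p, "val_recall": r, "val_f1": f1})
        if f1 > best_f1 or not val_set:  # no validation: keep latest state
            best_f1, best_snap, stale = f1, model.snapshot(), 0
        else:
            stale += 1
        if best_f1 >= 1.0:  # cannot improve further
            break
        if config.patience is not None and stale >= config.patience:
            break
    model.restore(best_snap)
    return model


def infer_schema(corpus: list[CorpusExample]) -> tuple[EntityTypeSet, RelationSchema]:
    """Recover entity-type and relation inventories from annotations."""
    types: list[str] = []
    rels: list[str] = []
    for ex in corpus:
        for sp in ex.spans:
            if sp.type not in types:
                types.append(sp.type)
        for tr in ex.triplets:
            if tr.relation not in rels:
                rels.append(tr.relation)
    return EntityTypeSet(sorted(types)), RelationSchema(sorted(rels))


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: ModelState, path: str) -> None:
    """Serialize schema, vocab, config and parameters to one ``.npz`` file."""
    meta = {
        "entity_types": list(model.entity_types),
        "relations": list(model.relations),
        "vocab": list(model.vocab.tokens),
        "config": asdict(model.config),
    }
    arrays = {k.replace(".", "__"): v.data for k, v in model.parameter_items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> ModelState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = TrainConfig(**meta["config"])
        model = ModelState(EntityTypeSet(meta["entity_types"]),
                           RelationSchema(meta["relations"]),
                           Vocab(tokens=tuple(meta["vocab"])), cfg)
        for k, t in model.parameter_items():
            t.data[...] = z[k.replace(".", "__")]
    return model
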