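"""Token encoder: trainable embeddings plus a small contextualizer.

The cascade's two stages share one encoder that maps a token sequence to one
context vector per token (the ``x_i`` fused into both the CRF emissions and
the object taggers).  At desk scale this is a trainable embedding table
followed by a contextualizer with two pathways:

* a *local* window — the previous and next token embeddings enter the
  output projection, carrying the entity-boundary evidence that start/end
  tagging and BIOE emission scores need;
* a *global* summary: a single-head scaled dot-product attention readout
  plus a masked mean pool of the sentence, carrying sentence-level evidence
  such as which relation trigger tokens are present (the mean pool keeps
  every trigger visible even when attention concentrates elsewhere).

Any encoder honouring the same contract (one finite d-vector per kept token,
differentiable in its parameters) can be dropped in behind :class:`Encoder`.
The contextualizer can be disabled (``use_context=False``), in which case
the encoding of token *i* depends only on token *i* — useful both as an
ablation and for testing the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax_lastaxis, tanh

__all__ = ["Vocab", "TokenEncoding", "Encoder", "build_vocab",
           "PAD_TOKEN", "UNK_TOKEN"]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass(frozen=True)
class Vocab:
    """Token -> contiguous integer ids; id 0 is padding, id 1 unknown."""

    tokens: tuple[str, ...]

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        idx = getattr(self, "_lookup", None)
        if idx is None:
            idx = {t: i for i, t in enumerate(self.tokens)}
            object.__setattr__(self, "_lookup", idx)
        return idx.get(token, self.unk_id)

    def encode_tokens(self, tokens: list[str]) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.intp)


def build_vocab(corpus) -> Vocab:
    """Build a vocabulary covering every token in the corpus.

    Ordering is deterministic — descending frequency, ties broken
    lexicographically — so two corpora with the same token multiset yield
    the same vocabulary.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    freq: dict[str, int] = {}
    for ex in corpus:
        for tok in ex.tokens:
            freq[tok] = freq.get(tok, 0) + 1
    ordered = sorted(freq, key=lambda t: (-freq[t], t))
    return Vocab(tokens=(PAD_TOKEN, UNK_TOKEN, *ordered))


@dataclass
class TokenEncoding:
    """One d-vector per kept token, with per-token validity flags."""

    vectors: Tensor  # (n, d) or (batch, n, d)
    mask: np.ndarray  # bool, same leading shape

    @property
    def length(self) -> int:
        return int(self.mask.sum(axis=-1) if self.mask.ndim == 1
                   else self.mask.sum())


class Encoder:
    """Embedding + optional single-head self-attention contextualizer.

    Parameters
    ----------
    vocab_size, dim : table geometry; ``dim`` (default 64) is the shared
        width ``d`` of context vectors and label embeddings.
    max_len : inputs longer than this are truncated (default 100 tokens).
    dropout : rate applied to the encoder output during training.
    use_context : disable to make token encodings strictly local.
    """

    def __init__(self, vocab_size: int, dim: int = 64, max_len: int = 100,
                 dropout: float = 0.2, use_context: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.max_len = max_len
        self.dropout = dropout
        self.use_context = use_context
        s = 1.0 / np.sqrt(dim)
        self.params: dict[str, Tensor] = {
            "emb": Tensor(rng.normal(0.0, s, (vocab_size, dim)), requires_grad=True),
            "Wq": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wk": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wv": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wo": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wprev": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wnext": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wg": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "Wm": Tensor(rng.normal(0.0, s, (dim, dim)), requires_grad=True),
            "bo": Tensor(np.zeros(dim), requires_grad=True),
        }
        # pad embedding row stays zero and receives no gradient updates
        self.params["emb"].data[0] = 0.0

    def encode_ids(self, ids: np.ndarray, mask: np.ndarray,
                   train: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
        """Encode a padded id batch ``(B, T)`` into vectors ``(B, T, d)``."""
        from .autodiff import concat, embedding

        x = embedding(self.params["emb"], ids)
        pre = x @ self.params["Wo"] + self.params["bo"]
        if self.use_context:
            B, T, d = x.shape
            zero = Tensor(np.zeros((B, 1, d)))
            x_prev = concat([zero, x[:, :-1, :]], axis=1) if T > 1 else zero
            x_next = concat([x[:, 1:, :], zero], axis=1) if T > 1 else zero
            q = x @ self.params["Wq"]
            k = x @ self.params["Wk"]
            v = x @ self.params["Wv"]
            scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.dim))
            # padded keys get -inf-ish scores so attention ignores them
            key_mask = np.where(mask[:, None, :], 0.0, -1e9)
            attn = softmax_lastaxis(scores + key_mask)
            lengths = mask.sum(axis=1, keepdims=True).astype(float)  # (B, 1)
            pooled = (x * mask[:, :, None].astype(float)).sum(axis=1) \
                * (1.0 / lengths)  # (B, d) masked mean of the sentence
            pre = (pre + x_prev @ self.params["Wprev"]
                   + x_next @ self.params["Wnext"]
                   + (attn @ v) @ self.params["Wg"]
                   + (pooled @ self.params["Wm"]).reshape(B, 1, d))
        h = tanh(pre)
        if train and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode encoding needs an rng for dropout")
            keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * keep
        return h

    def encode(self, tokens: list[str], vocab: Vocab,
               train: bool = False,
               rng: np.random.Generator | None = None) -> TokenEncoding:
        """Encode one sentence; inputs beyond ``max_len`` are truncated."""
        if not tokens:
            raise ValueError("cannot encode an empty token sequence")
        tokens = tokens[: self.max_len]
        ids = vocab.encode_tokens(tokens)[None, :]
        mask = np.ones_like(ids, dtype=bool)
        h = self.encode_ids(ids, mask, train=train, rng=rng)
        return TokenEncoding(vectors=h.reshape(len(tokens), self.dim),
                             mask=mask[0])

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return [(f"encoder.{k}", v) for k, v in self.params.items()]
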