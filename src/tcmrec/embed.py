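"""Skip-gram word embeddings and fixed-size embedding matrices.

Tokens from the clinical corpus are embedded with a skip-gram model trained
by negative sampling (dynamic context window, unigram^0.75 noise
distribution, linearly decaying learning rate — the standard word2vec
recipe).  A trained model then turns each patient's token sequence into a
``max_num_tokens x vector_size`` matrix with a validity mask: shorter
sequences are zero-padded, longer ones are clipped by dropping the tokens
with the oldest timestamps so the most recent evidence is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import TokenSequence

__all__ = ["EmbedConfig", "EmbeddingModel", "EmbeddingMatrix",
           "train_embeddings", "vectorize"]


@dataclass(frozen=True)
class EmbedConfig:
    min_count: int = 2
    vector_size: int = 100
    window: int = 5
    sg: int = 1       # skip-gram (the only architecture implemented)
    hs: int = 0       # negative sampling used as the training objective
    negative: int = 5
    epochs: int = 50
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.vector_size <= 0:
            raise ValueError("vector_size must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class EmbeddingModel:
    vocabulary: dict[str, int]
    vectors: np.ndarray  # |V| x vector_size

    @property
    def vector_size(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocabulary[token]]

    def save_word2vec(self, path: str | Path) -> None:
        """Persist in the word2vec text format (header line, then one
        token + floats per line)."""
        order = sorted(self.vocabulary, key=self.vocabulary.get)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(order)} {self.vector_size}\n")
            for tok in order:
                vals = " ".join(f"{v:.8g}" for v in self.vector(tok))
                fh.write(f"{tok} {vals}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            n, d = map(int, fh.readline().split())
            vocab: dict[str, int] = {}
            vecs = np.empty((n, d))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vecs[i] = [float(x) for x in parts[1 : d + 1]]
        return cls(vocabulary=vocab, vectors=vecs)


@dataclass
class EmbeddingMatrix:
    """Fixed-size transformer input: values (T x D) plus validity mask (T,).

    Rows where the mask is false are all-zero; they are either padding or
    out-of-vocabulary tokens (the mask is what disambiguates the two from
    genuine zero vectors).
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.values.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape[0] != self.values.shape[0]:
            raise ValueError("mask length must equal number of rows")


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _build_vocab(corpus: list[list[str]], min_count: int) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    vocab = {t: i for i, t in enumerate(kept)}
    freqs = np.array([counts[t] for t in kept], dtype=np.float64)
    return vocab, freqs


def train_embeddings(
    corpus: list[TokenSequence] | list[list[str]],
    cfg: EmbedConfig = EmbedConfig(),
) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling on a token corpus.

    Tokens occurring fewer than ``min_count`` times are excluded from the
    vocabulary.  Deterministic for a fixed config seed.
    """
    sents = [s.tokens if isinstance(s, TokenSequence) else list(s) for s in corpus]
    sents = [s for s in sents if s]
    if not sents:
        raise ValueError("cannot train embeddings on an empty corpus")
    vocab, freqs = _build_vocab(sents, cfg.min_count)
    V, D = len(vocab), cfg.vector_size
    rng = np.random.default_rng(cfg.seed)
    if V == 0:
        return EmbeddingModel(vocabulary={}, vectors=np.zeros((0, D)))
    W_in = (rng.random((V, D)) - 0.5) / D  # word2vec-style init
    W_out = np.zeros((V, D))
    noise = freqs**0.75
    noise /= noise.sum()

    encoded = [np.array([vocab[t] for t in s if t in vocab], dtype=np.int64) for s in sents]
    encoded = [e for e in encoded if len(e) >= 2]
    if not encoded:
        return EmbeddingModel(vocabulary=vocab, vectors=W_in)

    # pre-build (center, context) pairs once per epoch with a fresh dynamic
    # window draw, then do one vectorized SGD sweep per chunk
    total_steps = cfg.epochs
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * max(1e-4, 1.0 - epoch / total_steps)
        centers, contexts = [], []
        for e in encoded:
            b = rng.integers(1, cfg.window + 1, size=len(e))
            for i in range(len(e)):
                lo, hi = max(0, i - b[i]), min(len(e), i + b[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(e[i])
                        contexts.append(e[j])
        centers = np.array(centers, dtype=np.int64)
        contexts = np.array(contexts, dtype=np.int64)
        perm = rng.permutation(len(centers))
        centers, contexts = centers[perm], contexts[perm]
        # small chunks keep per-token repeat counts low, so summed updates at
        # the word2vec learning rate stay in the stable sequential-SGD regime
        # even when the vocabulary is small
        chunk = 64
        negs = rng.choice(V, size=(len(centers), cfg.negative), p=noise)
        for lo in range(0, len(centers), chunk):
            c = centers[lo : lo + chunk]
            o = contexts[lo : lo + chunk]
            neg = negs[lo : lo + chunk]
            vc = W_in[c]                       # (B, D)
            uo = W_out[o]                      # (B, D)
            un = W_out[neg]                    # (B, k, D)
            s_pos = _expit(np.einsum("bd,bd->b", vc, uo))
            s_neg = _expit(np.einsum("bd,bkd->bk", vc, un))
            g_pos = (s_pos - 1.0)[:, None]     # dL/d(vc.uo)
            grad_vc = g_pos * uo + np.einsum("bk,bkd->bd", s_neg, un)
            np.add.at(W_out, o, -lr * g_pos * vc)
            np.add.at(W_out, neg.ravel(),
                      (-lr * s_neg[:, :, None] * vc[:, None, :]).reshape(-1, W_out.shape[1]))
            np.add.at(W_in, c, -lr * grad_vc)
    return EmbeddingModel(vocabulary=vocab, vectors=W_in)


def clip_to_most_recent(seq: TokenSequence, cap: int) -> TokenSequence:
    """Drop the tokens with the oldest timestamps until ``len <= cap``."""
    n = len(seq)
    if n <= cap:
        return seq
    drop = n - cap
    return TokenSequence(tokens=seq.tokens[drop:], t_hours=seq.t_hours[drop:])


def vectorize(
    seq: TokenSequence,
    model: EmbeddingModel,
    max_num_tokens: int,
) -> EmbeddingMatrix:
    """Token sequence -> fixed-size embedding matrix.

    In-vocabulary tokens map to their vectors in sequence order;
    out-of-vocabulary tokens get a zero row with mask false.  Sequences
    longer than the cap lose their oldest-timestamp tokens; shorter ones are
    zero-padded at the end (mask false).
    """
    if max_num_tokens <= 0:
        raise ValueError("max_num_tokens must be positive")
    seq = clip_to_most_recent(seq, max_num_tokens)
    values = np.zeros((max_num_tokens, model.vector_size))
    mask = np.zeros(max_num_tokens, dtype=bool)
    for i, tok in enumerate(seq.tokens):
        if tok in model.vocabulary:
            values[i] = model.vector(tok)
            mask[i] = True
    return EmbeddingMatrix(values=values, mask=mask)
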