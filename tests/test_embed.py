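"""Skip-gram training and pad/clip vectorization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcmrec.embed import (EmbedConfig, EmbeddingModel, clip_to_most_recent,
                          train_embeddings, vectorize)
from tcmrec.features import TokenSequence


@pytest.fixture(scope="module")
def corpus():
    rng = np.random.default_rng(0)
    vocab = [f"tok{i}" for i in range(30)]
    return [
        [vocab[j] for j in rng.integers(0, 30, size=rng.integers(5, 20))]
        for _ in range(80)
    ]


@pytest.fixture(scope="module")
def model(corpus):
    return train_embeddings(corpus, EmbedConfig(vector_size=16, epochs=5, seed=1))


def pad_clip_oracle(seq: TokenSequence, model: EmbeddingModel, cap: int):
    """Brute force: stable-sort by timestamp, drop the earliest overflow,
    then map/pad row by row."""
    order = sorted(range(len(seq)), key=lambda i: seq.t_hours[i])
    keep = order[max(0, len(seq) - cap):]
    values = np.zeros((cap, model.vector_size))
    mask = np.zeros(cap, dtype=bool)
    for row, i in enumerate(keep):
        tok = seq.tokens[i]
        if tok in model.vocabulary:
            values[row] = model.vector(tok)
            mask[row] = True
    return values, mask


class TestTrainEmbeddings:
    def test_min_count_excludes_rare_tokens(self):
        corpus = [["common", "common", "rare"], ["common", "common"]]
        m = train_embeddings(corpus, EmbedConfig(min_count=2, vector_size=8,
                                                 epochs=2, seed=0))
        assert "common" in m.vocabulary and "rare" not in m.vocabulary

    def test_vector_dimension(self, model):
        assert model.vectors.shape[1] == 16
        assert np.isfinite(model.vectors).all()

    def test_deterministic(self, corpus):
        cfg = EmbedConfig(vector_size=8, epochs=3, seed=2)
        a = train_embeddings(corpus, cfg)
        b = train_embeddings(corpus, cfg)
        assert a.vocabulary == b.vocabulary
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], EmbedConfig())

    def test_shared_context_tokens_embed_closer(self):
        # distributional similarity: tokens appearing in interchangeable
        # contexts end up closer than tokens from disjoint contexts
        rng = np.random.default_rng(3)
        corpus = []
        for _ in range(300):
            u = rng.random()
            if u < 1 / 3:
                corpus.append(["a"] + [f"n{rng.integers(6)}" for _ in range(4)])
            elif u < 2 / 3:
                corpus.append(["b"] + [f"n{rng.integers(6)}" for _ in range(4)])
            else:
                corpus.append(["d"] + [f"m{rng.integers(6)}" for _ in range(4)])
        m = train_embeddings(corpus, EmbedConfig(vector_size=16, epochs=20,
                                                 seed=3, min_count=2))
        def cos(x, y):
            return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
        assert cos(m.vector("a"), m.vector("b")) > cos(m.vector("a"), m.vector("d"))

    def test_word2vec_text_roundtrip(self, model, tmp_path):
        path = tmp_path / "emb.txt"
        model.save_word2vec(path)
        again = EmbeddingModel.load_word2vec(path)
        assert again.vocabulary == model.vocabulary
        np.testing.assert_allclose(again.vectors, model.vectors, rtol=1e-6)


def seq_of(tokens, times=None):
    times = times if times is not None else [float(i) for i in range(len(tokens))]
    return TokenSequence(tokens=list(tokens), t_hours=list(times))


class TestVectorize:
    def test_padding_short_sequence(self, model):
        seq = seq_of([f"tok{i}" for i in range(10)])
        em = vectorize(seq, model, max_num_tokens=759)
        assert em.values.shape == (759, 16)
        assert em.mask[:10].all() and not em.mask[10:].any()
        assert not em.values[10:].any()

    def test_clipping_drops_oldest(self, model):
        tokens = [f"tok{i % 30}" for i in range(800)]
        em = vectorize(seq_of(tokens), model, max_num_tokens=759)
        ref_vals, ref_mask = pad_clip_oracle(seq_of(tokens), model, 759)
        np.testing.assert_array_equal(em.values, ref_vals)
        np.testing.assert_array_equal(em.mask, ref_mask)
        # newest token retained in the last row
        np.testing.assert_array_equal(em.values[-1], model.vector(tokens[-1]))

    def test_exact_cap_untouched(self, model):
        tokens = [f"tok{i % 30}" for i in range(64)]
        em = vectorize(seq_of(tokens), model, max_num_tokens=64)
        assert em.mask.all()
        np.testing.assert_array_equal(em.values[0], model.vector(tokens[0]))

    def test_oov_rows_zero_with_false_mask(self, model):
        em = vectorize(seq_of(["tok1", "never-seen", "tok2"]), model, 8)
        assert em.mask.tolist()[:3] == [True, False, True]
        assert not em.values[1].any()

    @pytest.mark.parametrize("n", [0, 1, 30, 64, 100])
    def test_shape_invariant(self, model, n):
        em = vectorize(seq_of([f"tok{i % 30}" for i in range(n)]), model, 64)
        assert em.values.shape == (64, 16) and em.mask.shape == (64,)

    @given(st.integers(0, 120))
    def test_matches_oracle_any_length(self, model, n):
        seq = seq_of([f"tok{i % 30}" if i % 7 else "oov" for i in range(n)])
        em = vectorize(seq, model, 64)
        ref_vals, ref_mask = pad_clip_oracle(seq, model, 64)
        np.testing.assert_array_equal(em.values, ref_vals)
        np.testing.assert_array_equal(em.mask, ref_mask)

    def test_clip_helper_keeps_most_recent(self):
        seq = seq_of(list("abcdef"), [0, 1, 2, 3, 4, 5])
        clipped = clip_to_most_recent(seq, 3)
        assert clipped.tokens == ["d", "e", "f"]
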