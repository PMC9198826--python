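"""Transformer classifier: forward contracts, decoding, training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcmrec.embed import EmbeddingMatrix
from tcmrec.model import (PrescriptionTransformer, TrainConfig,
                          TransformerConfig, decode, train_model,
                          tune_hyperparameters)

CFG = TransformerConfig.desk_scale(n_labels=6, max_num_tokens=12, model_dim=16,
                                   ffn_dim=32, hidden_dim=16)


@pytest.fixture(scope="module")
def net():
    return PrescriptionTransformer(CFG, seed=0)


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(4, 12, 16))
    M = np.ones((4, 12), dtype=bool)
    M[1, 8:] = False
    M[2, :] = False
    X[~M] = 0.0
    return X, M


class TestForward:
    def test_probabilities_in_open_unit_interval(self, net, batch):
        X, M = batch
        p = net.predict_proba(X, M)
        assert p.shape == (4, 6)
        assert (p > 0).all() and (p < 1).all()

    def test_all_padding_row_is_finite(self, net, batch):
        X, M = batch
        p = net.predict_proba(X, M)
        assert np.isfinite(p[2]).all()

    def test_inference_deterministic(self, net, batch):
        X, M = batch
        np.testing.assert_array_equal(net.predict_proba(X, M),
                                      net.predict_proba(X, M))

    def test_padding_content_cannot_leak(self, net, batch):
        X, M = batch
        X2 = X.copy()
        X2[~M] = np.random.default_rng(2).normal(size=(~M).sum() * 16).reshape(-1, 16)
        np.testing.assert_array_equal(net.predict_proba(X, M),
                                      net.predict_proba(X2, M))

    def test_shape_mismatch_rejected(self, net):
        with pytest.raises(ValueError, match="shaped"):
            net.predict_proba(np.zeros((1, 5, 16)), np.ones((1, 5), bool))

    def test_single_matrix_interface(self, net, batch):
        X, M = batch
        em = EmbeddingMatrix(values=X[0], mask=M[0])
        np.testing.assert_allclose(net.forward(em), net.predict_proba(X, M)[0])

    def test_eos_pooling_also_valid(self, batch):
        X, M = batch
        net = PrescriptionTransformer(
            TransformerConfig.desk_scale(n_labels=6, max_num_tokens=12,
                                         model_dim=16, ffn_dim=32,
                                         hidden_dim=16, pooling="eos"), seed=0)
        p = net.predict_proba(X, M)
        assert np.isfinite(p).all() and (0 < p).all() and (p < 1).all()


class TestDecode:
    def test_direct_example(self):
        assert decode(np.array([0.9, 0.2, 0.6]), 0.5) == {0, 2}

    def test_high_threshold_empty(self):
        assert decode(np.array([0.3, 0.4]), 1 - 1e-9) == set()

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(3)
        probs = rng.random(10)
        perm = rng.permutation(10)
        direct = decode(probs[perm], 0.5)
        relabeled = {int(np.flatnonzero(perm == i)[0]) for i in decode(probs, 0.5)}
        assert direct == relabeled

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_shrinking_threshold_grows_set(self, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        probs = np.linspace(0.05, 0.95, 13)
        assert decode(probs, hi) <= decode(probs, lo)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            decode(np.array([0.5]), bad)


def toy_dataset(n, seed, n_labels=6):
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        y = np.zeros(n_labels)
        y[rng.integers(n_labels)] = 1.0
        X = rng.normal(size=(12, 16)) + 2.0 * y.sum() * np.argmax(y)
        data.append((EmbeddingMatrix(values=X), y))
    return data


class TestTraining:
    def test_memorizes_single_sample(self):
        data = toy_dataset(1, seed=4)
        tcfg = TrainConfig(batch_size=1, epochs=120, learning_rate=5e-3, seed=4)
        model, history = train_model(data, CFG, tcfg)
        losses = [h["train_loss"] for h in history]
        assert losses[-1] < 0.05 * losses[0]
        probs = model.forward(data[0][0])
        assert decode(probs, 0.5) == {int(np.argmax(data[0][1]))}

    def test_loss_trace_recorded_per_epoch(self):
        model, history = train_model(toy_dataset(8, seed=5), CFG,
                                     TrainConfig(batch_size=4, epochs=3, seed=5))
        assert [h["epoch"] for h in history] == [0, 1, 2]

    def test_l2_shrinks_parameter_norm(self):
        data = toy_dataset(16, seed=6)
        def norm_with(l2):
            tcfg = TrainConfig(batch_size=8, epochs=15, l2_rate=l2, seed=6)
            model, _ = train_model(data, CFG, tcfg)
            return np.sqrt(sum(float((p.data ** 2).sum())
                               for p in model.parameters()))
        assert norm_with(0.01) < norm_with(0.0)

    def test_training_deterministic(self):
        data = toy_dataset(8, seed=7)
        tcfg = TrainConfig(batch_size=4, epochs=3, seed=7)
        m1, h1 = train_model(data, CFG, tcfg)
        m2, h2 = train_model(data, CFG, tcfg)
        assert h1 == h2
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model([], CFG, TrainConfig())

    def test_checkpoint_roundtrip(self, tmp_path, batch):
        X, M = batch
        model, _ = train_model(toy_dataset(4, seed=8), CFG,
                               TrainConfig(batch_size=4, epochs=2, seed=8))
        model.save(tmp_path / "ckpt")
        again = PrescriptionTransformer.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(model.predict_proba(X, M),
                                      again.predict_proba(X, M))


class TestTuning:
    def test_single_point_grid_returned(self):
        data = toy_dataset(12, seed=9)
        tcfg = TrainConfig(batch_size=6, epochs=2, cv_folds=3, seed=9)
        cfg_out, tcfg_out, trace = tune_hyperparameters(
            data, {"learning_rate": [0.002]}, CFG, tcfg)
        assert tcfg_out.learning_rate == 0.002
        assert len(trace) == 3  # one evaluation per fold

    def test_identical_winners_average_unchanged(self):
        # a grid where one point is clearly better on every fold
        data = toy_dataset(12, seed=10)
        tcfg = TrainConfig(batch_size=6, epochs=2, cv_folds=3, seed=10)
        _, tcfg_out, trace = tune_hyperparameters(
            data, {"epochs": [1, 2]}, CFG, tcfg)
        winners = {}
        for row in trace:
            f = row["fold"]
            if f not in winners or row["val_loss"] < winners[f][1]:
                winners[f] = (row["epochs"], row["val_loss"])
        vals = [v[0] for v in winners.values()]
        assert tcfg_out.epochs == int(round(np.mean(vals)))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(toy_dataset(6, seed=11), {}, CFG, TrainConfig())

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            tune_hyperparameters(toy_dataset(6, seed=11), {"zap": [1]}, CFG,
                                 TrainConfig(cv_folds=2))
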