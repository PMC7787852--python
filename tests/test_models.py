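"""Classifier building blocks: LSTM cell, architectures, training, gradients."""

import numpy as np
import pytest

import snorescreen as ss
from snorescreen.errors import ConfigError, DataError, DimensionError
from snorescreen.models import (
    CNN3_BLOCKS,
    CNN5_BLOCKS,
    _ce_loss_and_dlogits,
    _CNNNetwork,
    _LSTMNetwork,
)

from conftest import oracle_lstm_cell


def random_cell(rng, hidden, inp):
    mk = lambda: rng.standard_normal((hidden, hidden + inp))
    vk = lambda: rng.standard_normal(hidden)
    return ss.LSTMCellWeights(mk(), mk(), mk(), mk(), vk(), vk(), vk(), vk())


class TestLSTMCell:
    def test_all_zero_weights_and_state(self):
        w = ss.LSTMCellWeights(*[np.zeros((3, 5))] * 4, *[np.zeros(3)] * 4)
        h, c = ss.lstm_cell_step(np.ones(2), np.zeros(3), np.zeros(3), w)
        np.testing.assert_array_equal(h, 0.0)  # o*tanh(0) = 0 exactly
        np.testing.assert_array_equal(c, 0.0)

    def test_zero_weights_pass_half_of_previous_cell_state(self):
        w = ss.LSTMCellWeights(*[np.zeros((3, 5))] * 4, *[np.zeros(3)] * 4)
        c_prev = np.array([0.4, -1.0, 2.0])
        h, c = ss.lstm_cell_step(np.zeros(2), np.zeros(3), c_prev, w)
        np.testing.assert_allclose(c, 0.5 * c_prev)          # f = 0.5, i*g = 0
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            hidden = int(rng.integers(1, 5))
            inp = int(rng.integers(1, 5))
            w = random_cell(rng, hidden, inp)
            x = rng.standard_normal(inp)
            h0 = rng.standard_normal(hidden)
            c0 = rng.standard_normal(hidden)
            h, c = ss.lstm_cell_step(x, h0, c0, w)
            h_ref, c_ref = oracle_lstm_cell(
                x, h0, c0, w.W_f, w.W_i, w.W_c, w.W_o, w.b_f, w.b_i, w.b_c, w.b_o
            )
            np.testing.assert_allclose(h, h_ref, atol=1e-12)
            np.testing.assert_allclose(c, c_ref, atol=1e-12)

    def test_gate_outputs_bounded(self, rng):
        from scipy.special import expit

        w = random_cell(rng, 4, 3)
        z = np.concatenate([rng.standard_normal(4), rng.standard_normal(3)])
        for W, b in ((w.W_f, w.b_f), (w.W_i, w.b_i), (w.W_o, w.b_o)):
            g = expit(W @ z + b)
            assert np.all((g > 0) & (g < 1))
        assert np.all(np.abs(np.tanh(w.W_c @ z + w.b_c)) < 1)

    def test_dimension_mismatch(self, rng):
        w = random_cell(rng, 3, 2)
        with pytest.raises(DimensionError):
            ss.lstm_cell_step(np.zeros(5), np.zeros(3), np.zeros(3), w)


class TestBuildModel:
    def test_cnn3_block_table(self):
        model = ss.build_model(ss.ModelConfig("cnn3"))
        assert [b[:2] for b in model.config.conv_blocks] == [(20, 8), (10, 4), (5, 2)]
        assert all(b[2] == 64 for b in model.config.conv_blocks)
        assert [b[3] for b in model.config.conv_blocks] == [2, 2, 1]

    def test_cnn5_adds_two_small_blocks(self):
        model = ss.build_model(ss.ModelConfig("cnn5"))
        assert len(model.config.conv_blocks) == 5
        assert model.config.conv_blocks[3][:4] == (2, 2, 64, 1)
        assert model.config.conv_blocks[4][:4] == (2, 2, 64, 1)

    def test_wrong_blocks_rejected(self):
        with pytest.raises(ConfigError):
            ss.ModelConfig("cnn3", conv_blocks=((3, 3, 8, 1, 2),))

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigError):
            ss.ModelConfig("mlp")

    def test_lstm_runs_one_step_per_frame(self):
        net = _LSTMNetwork(40, 8, 2, np.random.default_rng(0))
        X = np.zeros((1, 298, 40), dtype=np.float32)
        _, _, cache = net.forward(X, want_cache=True)
        assert len(cache) == 298


class TestGradients:
    """Analytic gradients against central finite differences."""

    @staticmethod
    def check(net, X, y, rng, n_checks=8, tol=1e-5):
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        _, _, grads = net.loss_and_grads(X, y)
        for key in net.params:
            for idx in rng.integers(0, net.params[key].size, n_checks):
                p = net.params[key]
                orig = p.flat[idx]
                eps = 1e-4
                p.flat[idx] = orig + eps
                l1, _ = _ce_loss_and_dlogits(net.forward(X), y)
                p.flat[idx] = orig - eps
                l2, _ = _ce_loss_and_dlogits(net.forward(X), y)
                p.flat[idx] = orig
                num = (l1 - l2) / (2 * eps)
                ana = grads[key].flat[idx]
                assert abs(num - ana) <= tol * max(1.0, abs(num)), key

    def test_lstm_backprop(self, rng):
        net = _LSTMNetwork(5, 6, 2, np.random.default_rng(3))
        X = rng.standard_normal((4, 7, 5))
        self.check(net, X, np.array([0, 1, 1, 0]), rng)

    def test_cnn_backprop(self, rng):
        net = _CNNNetwork((12, 10), ((3, 3, 4, 2, 2), (2, 2, 3, 1, 2)), 2,
                          np.random.default_rng(3))
        X = rng.standard_normal((3, 12, 10))
        self.check(net, X, np.array([0, 1, 1]), rng)


@pytest.fixture(scope="module")
def separable_fixture():
    """Small linearly separable sequence dataset."""
    rng = np.random.default_rng(77)
    X = rng.standard_normal((60, 20, 8)).astype(np.float32)
    y = np.repeat([0, 1], 30)
    X[y == 1] += 1.5
    return X, y


@pytest.fixture(scope="module")
def trained_small_lstm(separable_fixture):
    X, y = separable_fixture
    config = ss.ModelConfig("lstm", lstm_hidden=16, input_shape=(20, 8))
    return ss.train(ss.build_model(config), X, y,
                    ss.TrainConfig(epochs=25, seed=5, validation_fraction=0.0))


class TestTraining:
    def test_separable_data_is_learned(self, trained_small_lstm):
        assert trained_small_lstm.history[-1]["train_acc"] >= 0.99

    def test_training_examples_are_memorized(self, separable_fixture,
                                             trained_small_lstm):
        X, y = separable_fixture
        probs = ss.predict_proba(trained_small_lstm, X)
        assert np.mean(np.argmax(probs, axis=1) == y) >= 0.99

    def test_single_class_rejected(self, separable_fixture):
        X, _ = separable_fixture
        config = ss.ModelConfig("lstm", lstm_hidden=8, input_shape=(20, 8))
        with pytest.raises(DataError):
            ss.train(ss.build_model(config), X, np.zeros(len(X), dtype=int))

    def test_same_seed_reproduces_history_and_predictions(self, separable_fixture):
        X, y = separable_fixture
        config = ss.ModelConfig("lstm", lstm_hidden=8, input_shape=(20, 8))
        cfg = ss.TrainConfig(epochs=2, seed=123)
        m1 = ss.train(ss.build_model(config), X, y, cfg)
        m2 = ss.train(ss.build_model(config), X, y, cfg)
        assert m1.history[0]["train_loss"] == m2.history[0]["train_loss"]
        np.testing.assert_array_equal(
            ss.predict_proba(m1, X), ss.predict_proba(m2, X)
        )

    def test_cnn_trains_on_full_size_input(self):
        local = np.random.default_rng(404)
        X = local.standard_normal((12, 298, 40)).astype(np.float32)
        y = np.array([0, 1] * 6)
        X[y == 1, 100:160] += 2.0
        model = ss.train(
            ss.build_model(ss.ModelConfig("cnn3")), X, y,
            ss.TrainConfig(epochs=10, seed=0, validation_fraction=0.0),
        )
        assert model.history[-1]["train_acc"] >= 0.9

    def test_normalization_is_stored_and_applied(self, separable_fixture,
                                                 trained_small_lstm):
        X, _ = separable_fixture
        assert trained_small_lstm.norm_mean.shape == (8,)
        # shifting inputs and mean by the same constant leaves outputs unchanged
        shifted = ss.TrainedModel(
            trained_small_lstm.config, trained_small_lstm.network,
            trained_small_lstm.norm_mean + 5.0, trained_small_lstm.norm_std,
        )
        np.testing.assert_allclose(
            ss.predict_proba(shifted, X + 5.0),
            ss.predict_proba(trained_small_lstm, X), atol=1e-6,
        )


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_small_lstm, rng):
        X = rng.standard_normal((5, 20, 8)).astype(np.float32)
        probs = ss.predict_proba(trained_small_lstm, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_single_clip_interface(self, separable_fixture, trained_small_lstm):
        X, y = separable_fixture
        label, prob = ss.predict(trained_small_lstm, X[0])
        assert label in (0, 1)
        assert 0.0 <= prob <= 1.0
        assert label == y[0]

    def test_shape_mismatch_rejected(self, trained_small_lstm, rng):
        with pytest.raises(DimensionError):
            ss.predict_proba(trained_small_lstm,
                             rng.standard_normal((2, 10, 8)).astype(np.float32))

    def test_row_permutation_changes_lstm_output(self, trained_small_lstm,
                                                 separable_fixture, rng):
        X, _ = separable_fixture
        x = X[0].copy()
        perm = x[rng.permutation(len(x))]
        p1 = ss.predict(trained_small_lstm, x)[1]
        p2 = ss.predict(trained_small_lstm, perm)[1]
        assert p1 != p2  # sequence order matters to the recurrent model


class TestPersistence:
    def test_save_load_preserves_predictions(self, tmp_path, separable_fixture,
                                             trained_small_lstm):
        X, _ = separable_fixture
        ss.save_model(tmp_path / "m.npz", trained_small_lstm)
        back = ss.load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            ss.predict_proba(back, X), ss.predict_proba(trained_small_lstm, X)
        )
        assert back.config.architecture == "lstm"
        assert len(back.history) == len(trained_small_lstm.history)
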