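"""LSTM cell equations, forward pass, gradients, training, and random search."""

import numpy as np
import pandas as pd
import pytest

from maizecast import lstm


def scalar_unrolled_forward(seq, params):
    """Independent step-by-step evaluation of the six gate equations."""

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    x = np.asarray(seq, dtype=float).T  # (T, k)
    states = [(np.zeros(l.hidden), np.zeros(l.hidden)) for l in params.layers]
    for t in range(x.shape[0]):
        inp = x[t]
        for li, layer in enumerate(params.layers):
            h, c = states[li]
            d = layer.hidden
            z = layer.W @ h + layer.U @ inp + layer.b
            i = sigmoid(z[:d])
            f = sigmoid(z[d : 2 * d])
            o = sigmoid(z[2 * d : 3 * d])
            g = np.tanh(z[3 * d :])
            c = f * c + i * g
            h = o * np.tanh(c)
            states[li] = (h, c)
            inp = h
    return float(states[-1][0] @ params.v + params.b_out)


class TestCellStep:
    def test_zero_params_zero_state(self):
        layer = lstm.LSTMLayerParams(np.zeros((4, 1)), np.zeros((4, 1)), np.zeros(4))
        h, c = lstm.lstm_cell_step(np.zeros(1), np.zeros(1), np.zeros(1), layer)
        assert h == pytest.approx(0.0)
        assert c == pytest.approx(0.0)

    def test_zero_weights_nonzero_cell(self):
        """Gates sit at 0.5, so c = 0.5*2 = 1 and h = 0.5*tanh(1)."""
        layer = lstm.LSTMLayerParams(np.zeros((4, 1)), np.zeros((4, 1)), np.zeros(4))
        h, c = lstm.lstm_cell_step(np.zeros(1), np.zeros(1), np.array([2.0]), layer)
        assert c[0] == pytest.approx(1.0)
        assert h[0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-9)
        assert h[0] == pytest.approx(0.380797, abs=1e-6)

    def test_hidden_state_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(8)
        layer = lstm.LSTMLayerParams(
            rng.normal(size=(12, 3)), rng.normal(size=(12, 5)), rng.normal(size=12)
        )
        for _ in range(20):
            h, _ = lstm.lstm_cell_step(
                rng.normal(size=5) * 10, rng.normal(size=3), rng.normal(size=3) * 5, layer
            )
            assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_raises(self):
        layer = lstm.LSTMLayerParams(np.zeros((8, 2)), np.zeros((8, 3)), np.zeros(8))
        with pytest.raises(ValueError):
            lstm.lstm_cell_step(np.zeros(2), np.zeros(2), np.zeros(2), layer)


class TestForward:
    def test_zero_params_predicts_output_bias(self):
        p = lstm.init_params(3, 4, n_layers=2, seed=0, n_time=5)
        for l in p.layers:
            l.W[:], l.U[:], l.b[:] = 0, 0, 0
        p.v[:] = 0
        p.b_out[...] = 7.25
        assert lstm.lstm_forward(np.ones((3, 5)), p) == pytest.approx(7.25)

    def test_single_step_equals_cell_plus_output(self):
        rng = np.random.default_rng(1)
        p = lstm.init_params(3, 4, n_layers=1, seed=2, n_time=1)
        x = rng.normal(size=(3, 1))
        h, _ = lstm.lstm_cell_step(x[:, 0], np.zeros(4), np.zeros(4), p.layers[0])
        assert lstm.lstm_forward(x, p) == pytest.approx(float(h @ p.v + p.b_out), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scalar_unrolled_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = lstm.init_params(2, 2, n_layers=2, seed=seed + 100, n_time=3)
        seq = rng.normal(size=(2, 3))
        assert lstm.lstm_forward(seq, p) == pytest.approx(
            scalar_unrolled_forward(seq, p), abs=1e-10
        )

    def test_oracle_equivalence_random_instances(self):
        """Batch forward equals the six-equation scalar oracle on 100 draws."""
        rng = np.random.default_rng(9)
        for trial in range(100):
            k = int(rng.integers(1, 4))
            d = int(rng.integers(1, 4))
            T = int(rng.integers(1, 5))
            p = lstm.init_params(k, d, n_layers=int(rng.integers(1, 3)), seed=trial, n_time=T)
            seq = rng.normal(size=(k, T))
            assert lstm.lstm_forward(seq, p) == pytest.approx(
                scalar_unrolled_forward(seq, p), abs=1e-10
            )

    def test_wrong_length_rejected(self):
        p = lstm.init_params(3, 4, seed=0, n_time=5)
        with pytest.raises(ValueError):
            lstm.lstm_forward(np.ones((3, 7)), p)

    def test_truncated_forward_equals_sliced_oracle(self):
        """A model trained at 122 days scores exactly the sliced sequence."""
        rng = np.random.default_rng(11)
        p = lstm.init_params(4, 3, seed=12, n_time=122)
        full = rng.normal(size=(4, 214))
        assert lstm.lstm_forward(full[:, :122], p) == pytest.approx(
            scalar_unrolled_forward(full[:, :122], p), abs=1e-10
        )
        with pytest.raises(ValueError):
            lstm.lstm_forward(full, p)


class TestGradients:
    def test_finite_difference_check(self):
        """BPTT gradient matches central differences to 1e-4 relative error."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3, 2))
        y = rng.normal(size=5)
        p = lstm.init_params(2, 2, n_layers=2, seed=5, n_time=3)
        _, grads = lstm.loss_and_gradients(X, y, p, training=False)
        worst = 0.0
        for ai, a in enumerate(p.arrays()):
            flat, g = a.reshape(-1), grads[ai].reshape(-1)
            for j in range(flat.size):
                eps = 1e-5
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = lstm.loss_and_gradients(X, y, p, training=False)
                flat[j] = orig - eps
                lm, _ = lstm.loss_and_gradients(X, y, p, training=False)
                flat[j] = orig
                fd = (lp - lm) / (2 * eps)
                worst = max(worst, abs(fd - g[j]) / max(1e-6, abs(fd) + abs(g[j])))
        assert worst < 1e-4

    def test_chunked_gradients_match_single_pass(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 4, 3))
        y = rng.normal(size=7)
        p = lstm.init_params(3, 2, seed=6, n_time=4)
        loss_a, grads_a = lstm.loss_and_gradients(X, y, p, training=False)
        old = lstm._CHUNK
        try:
            lstm._CHUNK = 3
            loss_b, grads_b = lstm.loss_and_gradients(X, y, p, training=False)
        finally:
            lstm._CHUNK = old
        assert loss_a == pytest.approx(loss_b, rel=1e-12)
        for ga, gb in zip(grads_a, grads_b):
            np.testing.assert_allclose(ga, gb, rtol=1e-9, atol=1e-12)


class TestTraining:
    def _toy(self, n=80, T=6, k=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, T, k))
        y = 2.0 * X[:, -1, 0] + 0.1 * rng.normal(size=n)
        return X, y

    def test_constant_targets_learn_the_constant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5, 2))
        y = np.full(60, 137.0)
        cfg = lstm.TrainConfig(hidden=4, epochs=30, batch_size=16, dropout=0.0,
                               learning_rate=1e-2, patience=None)
        params, hist = lstm.train(X, y, cfg, seed=3)
        pred = lstm.predict(X, params)
        assert float(np.mean((pred - y) ** 2)) < 1.0

    def test_loss_decreases_on_learnable_signal(self):
        X, y = self._toy()
        cfg = lstm.TrainConfig(hidden=8, epochs=25, batch_size=16, dropout=0.0, patience=None)
        params, hist = lstm.train(X, y, cfg, seed=4)
        assert np.isfinite(hist["train_mse"]).all()
        assert hist["train_mse"].iloc[-1] < hist["train_mse"].iloc[0]

    def test_deterministic_given_seed(self):
        X, y = self._toy(n=40)
        cfg = lstm.TrainConfig(hidden=4, epochs=3, batch_size=16, dropout=0.2, patience=None)
        p1, h1 = lstm.train(X, y, cfg, seed=9)
        p2, h2 = lstm.train(X, y, cfg, seed=9)
        for a, b in zip(p1.arrays(), p2.arrays()):
            np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(h1, h2)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises_with_diagnostic(self):
        X, y = self._toy(n=40)
        cfg = lstm.TrainConfig(hidden=4, epochs=10, batch_size=8, optimizer="sgd",
                               learning_rate=1e6, momentum=0.1, patience=None)
        with pytest.raises(lstm.TrainingDiverged):
            lstm.train(X, y, cfg, seed=1, standardize_target=False)


class TestRandomSearch:
    def _data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 5, 2))
        y = X[:, -1, 0]
        return X[:40], y[:40], X[40:], y[40:]

    def test_budget_one_returns_single_config(self):
        Xt, yt, Xv, yv = self._data()
        cfg, board = lstm.random_search(Xt, yt, Xv, yv, lstm.SearchSpace(), budget=1,
                                        seed=0, epochs=1)
        assert len(board) == 1
        assert isinstance(cfg, lstm.TrainConfig)

    def test_samples_come_from_printed_choice_sets(self):
        space = lstm.SearchSpace()
        rng = np.random.default_rng(7)
        for _ in range(50):
            cfg = space.sample(rng, epochs=1, patience=None)
            assert cfg.hidden in space.hidden_nodes
            assert cfg.batch_size in space.batch_size
            assert cfg.dropout in space.dropout
            assert cfg.learning_rate in space.learning_rate
            assert cfg.momentum in space.momentum
            assert cfg.decay in space.decay
            assert cfg.optimizer in space.optimizers

    def test_leaderboard_sorted_and_deterministic(self):
        Xt, yt, Xv, yv = self._data()
        space = lstm.SearchSpace(hidden_nodes=(4, 8), batch_size=(16,))
        cfg1, b1 = lstm.random_search(Xt, yt, Xv, yv, space, budget=4, seed=3, epochs=2)
        cfg2, b2 = lstm.random_search(Xt, yt, Xv, yv, space, budget=4, seed=3, epochs=2)
        assert (b1["val_mse"].diff().dropna() >= 0).all()
        pd.testing.assert_frame_equal(b1, b2)

    def test_empty_budget_rejected(self):
        Xt, yt, Xv, yv = self._data()
        with pytest.raises(ValueError):
            lstm.random_search(Xt, yt, Xv, yv, lstm.SearchSpace(), budget=0, seed=0)
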