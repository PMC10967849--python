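"""LSTM cell equations, forward pass, training and prediction."""

import math

import numpy as np
import pytest

from imugait.events import EVENT_ORDER
from imugait.lstm import (
    HeadParams,
    LstmParams,
    TrainConfig,
    _backward,
    _forward_cached,
    cell_step,
    forward,
    init_params,
    load_model,
    predict_phase,
    save_model,
    softmax,
    train,
)


def _sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def cell_step_scalar_oracle(params, h_prev, C_prev, x):
    """Elementwise hand evaluation of the five gate equations."""
    H = params.hidden_size
    a = list(h_prev) + list(x)
    h_out, C_out = [], []
    for j in range(H):
        zf = sum(params.W["f"][j, k] * a[k] for k in range(len(a))) + params.b["f"][j]
        zi = sum(params.W["i"][j, k] * a[k] for k in range(len(a))) + params.b["i"][j]
        zo = sum(params.W["o"][j, k] * a[k] for k in range(len(a))) + params.b["o"][j]
        zc = sum(params.W["c"][j, k] * a[k] for k in range(len(a))) + params.b["c"][j]
        f, i, o = _sigmoid(zf), _sigmoid(zi), _sigmoid(zo)
        C = f * C_prev[j] + i * math.tanh(zc)
        C_out.append(C)
        h_out.append(o * math.tanh(C))
    return np.array(h_out), np.array(C_out)


def random_params(rng, hidden=3, inputs=4):
    W = {g: rng.normal(size=(hidden, hidden + inputs)) for g in "fioc"}
    b = {g: rng.normal(size=hidden) for g in "fioc"}
    return LstmParams(W, b)


class TestCellStep:
    def test_zero_weights_halve_cell_state(self):
        params = LstmParams(
            W={g: np.zeros((2, 5)) for g in "fioc"},
            b={g: np.zeros(2) for g in "fioc"},
        )
        c = np.array([0.8, -0.4])
        h, C = cell_step(params, np.zeros(2), c, np.zeros(3))
        assert np.allclose(C, 0.5 * c)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * c))

    def test_zero_state_zero_weights_give_zero_hidden(self):
        params = LstmParams(
            W={g: np.zeros((2, 5)) for g in "fioc"},
            b={g: np.zeros(2) for g in "fioc"},
        )
        h, C = cell_step(params, np.zeros(2), np.zeros(2), np.zeros(3))
        assert np.allclose(h, 0.0)
        assert np.allclose(C, 0.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            params = random_params(rng)
            h_prev, C_prev = rng.normal(size=3), rng.normal(size=3)
            x = rng.normal(size=4)
            h, C = cell_step(params, h_prev, C_prev, x)
            h_ref, C_ref = cell_step_scalar_oracle(params, h_prev, C_prev, x)
            assert np.allclose(h, h_ref, atol=1e-10)
            assert np.allclose(C, C_ref, atol=1e-10)

    def test_shape_mismatch_names_offender(self):
        params = random_params(np.random.default_rng(1))
        with pytest.raises(ValueError, match="W_"):
            cell_step(params, np.zeros(3), np.zeros(3), np.zeros(9))

    def test_mismatched_gate_shapes_rejected(self):
        W = {g: np.zeros((2, 5)) for g in "fioc"}
        W["o"] = np.zeros((3, 5))
        with pytest.raises(ValueError, match="shape"):
            LstmParams(W, {g: np.zeros(2) for g in "fioc"})


class TestForward:
    def test_output_on_probability_simplex(self):
        rng = np.random.default_rng(2)
        params, head = init_params(input_size=4, hidden_size=3, fc_size=2, seed=3)
        for _ in range(5):
            p = forward(params, head, rng.normal(size=(5, 4)))
            assert p.shape == (6,)
            assert np.all(p >= 0)
            assert abs(p.sum() - 1.0) < 1e-6

    def test_zero_output_weights_give_uniform(self):
        params, head = init_params(input_size=4, hidden_size=3, seed=4)
        head.W2[:] = 0.0
        head.b2[:] = 0.0
        p = forward(params, head, np.random.default_rng(5).normal(size=(5, 4)))
        assert np.allclose(p, 1.0 / 6.0)

    def test_composition_matches_stepwise_oracle(self):
        rng = np.random.default_rng(6)
        params, head = init_params(input_size=4, hidden_size=2, fc_size=3, seed=7)
        seq = rng.normal(size=(5, 4))
        h, C = np.zeros(2), np.zeros(2)
        for t in range(5):
            h, C = cell_step_scalar_oracle(params, h, C, seq[t])
        r = np.maximum(head.W1 @ h + head.b1, 0.0)
        p_ref = softmax(head.W2 @ r + head.b2)
        assert np.allclose(forward(params, head, seq), p_ref, atol=1e-10)

    def test_wrong_sequence_width_raises(self):
        params, head = init_params(input_size=4, hidden_size=2)
        with pytest.raises(ValueError):
            forward(params, head, np.zeros((5, 7)))

    def test_prediction_ignores_samples_outside_window(self):
        # causality: a prediction windowed at time t is unaffected by any
        # change to the stream after t
        from imugait.features import make_sequences

        rng = np.random.default_rng(8)
        params, head = init_params(input_size=4, hidden_size=3, seed=9)
        X = rng.normal(size=(30, 4))
        seqs, _ = make_sequences(X, n=5)
        p_t = forward(params, head, seqs[10])  # window ends at sample 14
        X2 = X.copy()
        X2[15:] += 100.0
        seqs2, _ = make_sequences(X2, n=5)
        assert np.array_equal(forward(params, head, seqs2[10]), p_t)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(10)
        params, head = init_params(input_size=3, hidden_size=2, fc_size=2, n_classes=3,
                                   seed=11, classes=("a", "b", "c"))
        X = rng.normal(size=(4, 5, 3))
        onehot = np.eye(3)[rng.integers(0, 3, size=4)]

        def loss():
            p, _ = _forward_cached(params, head, X)
            return -float(np.sum(onehot * np.log(p + 1e-12))) / len(X)

        p, cache = _forward_cached(params, head, X)
        gW, gb, gW1, gb1, gW2, gb2 = _backward(params, head, X, p, onehot, cache)
        eps = 1e-6
        for tensor, grad in [(params.W["f"], gW["f"]), (params.W["c"], gW["c"]),
                             (params.b["i"], gb["i"]), (head.W1, gW1), (head.b2, gb2)]:
            it = np.nditer(tensor, flags=["multi_index"])
            for _ in range(min(tensor.size, 6)):
                idx = it.multi_index
                orig = tensor[idx]
                tensor[idx] = orig + eps
                lp = loss()
                tensor[idx] = orig - eps
                lm = loss()
                tensor[idx] = orig
                assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
                it.iternext()


class TestTrain:
    def _toy_sequences(self, n=40, seed=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5, 4)) * 0.1
        y = np.array(["pos" if k % 2 == 0 else "neg" for k in range(n)], dtype=object)
        X[::2, :, 0] += 2.0  # class "pos" has a shifted first channel
        return X, y

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = self._toy_sequences()
        cfg = TrainConfig(epochs=50, batch_size=8, hidden_size=4, fc_size=4, seed=13)
        params, head, losses = train(cfg, X, y, classes=("neg", "pos"))
        pred = predict_phase(params, head, X)
        assert np.mean(pred == y) == 1.0
        assert losses[-1] < losses[0]

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_missing_class_warns_by_name(self):
        X, y = self._toy_sequences()
        cfg = TrainConfig(epochs=1, batch_size=8, hidden_size=2, seed=14)
        with pytest.warns(UserWarning, match="L-HMax"):
            train(cfg, X, np.where(y == "pos", "L-HS", "R-TO").astype(object))

    def test_same_seed_reproduces_weights(self):
        X, y = self._toy_sequences()
        cfg = TrainConfig(epochs=5, batch_size=8, hidden_size=3, seed=15)
        p1, h1, _ = train(cfg, X, y, classes=("neg", "pos"))
        p2, h2, _ = train(cfg, X, y, classes=("neg", "pos"))
        assert np.array_equal(p1.W["f"], p2.W["f"])
        assert np.array_equal(h1.W2, h2.W2)


class TestPredictPhase:
    def test_head_biased_to_one_class_always_wins(self):
        params, head = init_params(input_size=4, hidden_size=3, seed=16)
        head.W2[:] = 0.0
        head.b2[:] = 0.0
        head.b2[3] = 5.0
        seq = np.random.default_rng(17).normal(size=(5, 4))
        assert predict_phase(params, head, seq) == EVENT_ORDER[3]

    def test_exact_tie_breaks_to_lowest_index(self):
        params, head = init_params(input_size=4, hidden_size=3, seed=18)
        head.W2[:] = 0.0
        head.b2[:] = 0.0  # uniform probabilities: a six-way tie
        seq = np.zeros((5, 4))
        assert predict_phase(params, head, seq) == EVENT_ORDER[0]

    def test_argmax_matches_brute_force_max(self):
        rng = np.random.default_rng(19)
        params, head = init_params(input_size=4, hidden_size=3, seed=20)
        seqs = rng.normal(size=(50, 5, 4))
        preds = predict_phase(params, head, seqs)
        probs = forward(params, head, seqs)
        for k in range(len(seqs)):
            best = max(range(6), key=lambda j: probs[k, j])
            assert preds[k] == head.classes[best]

    def test_save_load_round_trip(self, tmp_path):
        params, head = init_params(input_size=4, hidden_size=3, seed=21)
        save_model(tmp_path / "m", params, head)
        p2, h2 = load_model(tmp_path / "m")
        seq = np.random.default_rng(22).normal(size=(5, 4))
        assert np.array_equal(forward(params, head, seq), forward(p2, h2, seq))


class TestHoldoutLearnability:
    def test_held_out_subject_phase_accuracy(self, phase_holdout_report):
        report, _losses = phase_holdout_report
        assert report.accuracy >= 0.90

    def test_training_loss_decreases(self, phase_holdout_report):
        _report, losses = phase_holdout_report
        assert losses[-1] < 0.5 * losses[0]
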