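"""Loss closed forms, network construction, training behaviour, SVM baseline."""

import math

import numpy as np
import pytest

from gaitdx import dataset as ds
from gaitdx import models as md
from gaitdx._nn import softmax


def examples_from_arrays(x, forms):
    return [
        ds.LabeledExample(xi, ds.one_hot(f), f"p{i}", f"t{i}")
        for i, (xi, f) in enumerate(zip(x, forms))
    ]


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.eye(4)
        pred = np.clip(y, 1e-12, 1.0 - 3e-12)
        pred /= pred.sum(axis=1, keepdims=True)
        assert md.categorical_cross_entropy(y, pred) <= 1e-11

    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_uniform_predictor_closed_form(self, n):
        y = np.eye(4)[np.arange(n) % 4]
        pred = np.full((n, 4), 0.25)
        expected = math.log(4.0) / 4.0
        assert md.categorical_cross_entropy(y, pred) == pytest.approx(expected, abs=1e-12)

    def test_hand_computed_double_sum(self):
        y = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
        p = np.array([[0.7, 0.1, 0.1, 0.1], [0.2, 0.2, 0.5, 0.1]])
        expected = -(math.log(0.7) + math.log(0.5)) / (2 * 4)
        assert md.categorical_cross_entropy(y, p) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_clipped_finite(self):
        y = np.array([[1.0, 0, 0, 0]])
        p = np.array([[0.0, 0.5, 0.25, 0.25]])
        loss = md.categorical_cross_entropy(y, p)
        assert np.isfinite(loss)
        assert loss == pytest.approx(-math.log(1e-12) / 4, rel=1e-6)


class TestMlpConstruction:
    def test_default_parameter_count_closed_form(self):
        model = md.build_mlp(md.MlpConfig(), seed=0)
        sizes = [1620, 256, 128, 64, 32, 4]
        expected = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
        assert model.n_parameters() == expected

    def test_empty_hidden_is_logistic_regression(self):
        model = md.build_mlp(md.MlpConfig(hidden_sizes=()), seed=0)
        assert model.n_parameters() == 1620 * 4 + 4

    def test_layer_growth_rule(self):
        assert md.MlpConfig.layer_growth(4) == (32, 64, 128, 256)

    def test_forward_outputs_distributions(self):
        model = md.build_mlp(seed=1)
        x = np.random.default_rng(0).normal(size=(7, 1620))
        probs = model.predict_proba(x)
        assert probs.shape == (7, 4)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestMlpTraining:
    def separable_examples(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        forms = rng.integers(1, 5, size=n)
        x = rng.normal(size=(n, 1620)) * 0.1
        for i, f in enumerate(forms):
            x[i, f - 1] += 8.0  # one giveaway feature per class
        return examples_from_arrays(x, forms)

    def test_separable_data_stops_before_cap(self):
        train = self.separable_examples()
        model = md.build_mlp(md.MlpConfig(hidden_sizes=(32,), dropout_rate=0.0), seed=0)
        model, trace = md.train_mlp(model, train, md.TrainConfig(seed=0))
        assert trace[-1] < 0.10
        assert len(trace) < 500

    def test_epoch_cap_is_respected(self):
        rng = np.random.default_rng(1)
        train = examples_from_arrays(
            rng.normal(size=(40, 1620)), rng.integers(1, 5, size=40)
        )
        cfg = md.TrainConfig(seed=0, mlp_max_epochs=3, mlp_loss_threshold=1e-9)
        model = md.build_mlp(md.MlpConfig(hidden_sizes=(8,)), seed=0)
        _, trace = md.train_mlp(model, train, cfg)
        assert len(trace) == 3

    def test_fixed_seed_reproduces_loss_trace(self):
        train = self.separable_examples(n=60, seed=2)
        cfg = md.TrainConfig(seed=7, mlp_max_epochs=5, mlp_loss_threshold=0.0)
        traces = []
        for _ in range(2):
            model = md.build_mlp(md.MlpConfig(hidden_sizes=(16,)), seed=3)
            _, trace = md.train_mlp(model, train, cfg)
            traces.append(trace)
        assert traces[0] == traces[1]


class TestLstm:
    def window_examples(self, n, seed, separation=3.0):
        rng = np.random.default_rng(seed)
        forms = rng.integers(1, 5, size=n)
        x = rng.normal(size=(n, 75, 81))
        t = np.arange(75)
        for i, f in enumerate(forms):
            # class signature: a constant offset plus a form-specific rhythm
            x[i, :, f - 1] += separation
            x[i, :, 4:8] += separation * np.sin(2 * np.pi * f * t / 75)[:, None]
        return examples_from_arrays(x, forms)

    def test_forward_outputs_distributions(self):
        model = md.build_lstm(md.LstmConfig(recurrent_units=8, fc_sizes=(8,)), seed=0)
        x = np.random.default_rng(0).normal(size=(5, 75, 81))
        probs = model.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_untrained_predictions_near_uniform_on_constant_input(self):
        model = md.build_lstm(md.LstmConfig(recurrent_units=16, fc_sizes=(16,)), seed=0)
        x = np.full((6, 75, 81), 0.5)
        probs = model.predict_proba(x)
        assert probs.max() <= 0.35

    def test_learns_well_separated_sequences(self):
        train = self.window_examples(600, seed=0)
        model = md.build_lstm(md.LstmConfig(recurrent_units=32, fc_sizes=(16,)), seed=0)
        model, trace = md.train_lstm(model, train, md.TrainConfig(seed=0))
        assert len(trace) == 15
        preds = model.predict(train)
        acc = np.mean([p.form == e.form for p, e in zip(preds, train)])
        assert acc > 0.9


class TestSvm:
    def blob_examples(self, n, seed, forms=(1, 2), sep=1.0):
        rng = np.random.default_rng(seed)
        labels = rng.choice(forms, size=n)
        x = rng.normal(size=(n, 1620))
        for i, f in enumerate(labels):
            x[i] += sep if f == forms[0] else -sep
        return examples_from_arrays(x, labels)

    def test_separable_blobs_perfectly_classified(self):
        train = self.blob_examples(60, seed=0)
        test = self.blob_examples(30, seed=1)
        svm = md.train_svm_baseline(train)
        preds = svm.predict(test)
        assert all(p.form == e.form for p, e in zip(preds, test))

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(2)
        train = examples_from_arrays(
            rng.normal(size=(200, 1620)), rng.integers(1, 5, size=200)
        )
        test = examples_from_arrays(
            rng.normal(size=(120, 1620)), rng.integers(1, 5, size=120)
        )
        svm = md.train_svm_baseline(train)
        acc = np.mean([p.form == e.form for p, e in zip(svm.predict(test), test)])
        sigma = math.sqrt(0.25 * 0.75 / 120)
        assert abs(acc - 0.25) <= 4 * sigma

    def test_deterministic(self):
        train = self.blob_examples(40, seed=3)
        test = self.blob_examples(20, seed=4)
        p1 = [p.form for p in md.train_svm_baseline(train).predict(test)]
        p2 = [p.form for p in md.train_svm_baseline(train).predict(test)]
        assert p1 == p2

    def test_single_class_rejected(self):
        train = self.blob_examples(20, seed=5, forms=(3, 3))
        with pytest.raises(ValueError):
            md.train_svm_baseline(train)


def test_gradients_match_finite_differences():
    from gaitdx._nn import LSTM, Dense, ReLU, Sequential

    rng = np.random.default_rng(0)
    net = Sequential([LSTM(5, 7, rng), Dense(7, 6, rng), ReLU(), Dense(6, 3, rng)])
    x = rng.normal(size=(4, 6, 5))
    y = np.eye(3)[rng.integers(0, 3, size=4)]

    def loss():
        return md.categorical_cross_entropy(y, softmax(net.forward(x)))

    probs = softmax(net.forward(x))
    net.backward((probs - y) / y.size)
    grads = [g.copy() for _, g in net.params()]
    eps = 1e-6
    for (p, _), g in zip(net.params(), grads):
        for _ in range(20):
            idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-5 * max(1.0, abs(num))
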