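"""LSTM unit equations, BiLSTM training, and the sklearn-backed classifiers."""

import math

import numpy as np
import pytest

from crawlemg.classify import (BiLSTMClassifier, ClassifierSpec,
                               LSTMUnitParams, SklearnEnvelopeClassifier,
                               bilstm_forward, flatten_features, lstm_unit_step,
                               predict, train)
from crawlemg.features import EnvelopeCycle

SMALL_BILSTM = ClassifierSpec(kind="bilstm", hidden_units=16, epochs=30,
                              time_steps=50, dense_sizes=(32, 16))


def scalar_lstm_reference(params, x, h_prev, c_prev):
    """Independent pure-Python scalar-loop LSTM step (no numpy linear algebra)."""
    H = params.hidden_size
    D = np.atleast_2d(params.W_fx).shape[1]
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))

    def lin(Wh, Wx, b, j):
        Wh = np.atleast_2d(Wh)
        Wx = np.atleast_2d(Wx)
        return (sum(Wh[j][k] * h_prev[k] for k in range(H))
                + sum(Wx[j][d] * x[d] for d in range(D)) + b[j])

    h, c = [], []
    for j in range(H):
        f = sig(lin(params.W_fh, params.W_fx, params.b_f, j))
        u = sig(lin(params.W_uh, params.W_ux, params.b_u, j))
        o = sig(lin(params.W_oh, params.W_ox, params.b_o, j))
        cbar = math.tanh(lin(params.W_ch, params.W_cx, params.b_c, j))
        cj = f * c_prev[j] + u * cbar
        c.append(cj)
        h.append(o * math.tanh(cj))
    return np.array(h), np.array(c)


def _toy_dataset(rng, n_per_class=12, n_points=200, n_channels=6):
    """Two well-separated envelope classes: early vs late burst."""
    samples = []
    t = np.linspace(0, 1, n_points)
    for label, center in (("A", 0.25), ("B", 0.75)):
        for _ in range(n_per_class):
            c = center + rng.normal(0, 0.02)
            burst = np.exp(-0.5 * ((t - c) / 0.08) ** 2)
            vals = np.stack([burst + 0.05 * rng.normal(size=n_points)
                             for _ in range(n_channels)], axis=1)
            vals = (vals - vals.mean(0)) / vals.std(0)
            samples.append(EnvelopeCycle(vals, label, "P1", "low"))
    return samples


class TestLSTMUnitStep:
    def test_all_zero_parameters_give_zero_states(self):
        p = LSTMUnitParams.zeros(3, 2)
        h, c = lstm_unit_step(p, [1.0, -2.0], np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(c, 0.0)

    def test_one_dimensional_worked_case(self):
        # hand evaluation: c̄ = tanh(1), c = σ(0)·c̄, h = σ(0)·tanh(c)
        p = LSTMUnitParams.zeros(1, 1)
        p.W_cx = np.array([[1.0]])
        h, c = lstm_unit_step(p, [1.0], np.zeros(1), np.zeros(1))
        cbar = math.tanh(1.0)
        assert c[0] == pytest.approx(0.5 * cbar, abs=1e-5)
        assert h[0] == pytest.approx(0.5 * math.tanh(0.5 * cbar), abs=1e-5)
        assert h[0] == pytest.approx(0.18170, abs=1e-5)

    def test_matches_scalar_reference_on_random_instances(self, rng):
        for _ in range(10):
            H, D = rng.integers(1, 5), rng.integers(1, 4)
            p = LSTMUnitParams(
                *(rng.normal(size=(H, H)) if n.endswith("h") else rng.normal(size=(H, D))
                  for n in ("W_fh", "W_fx", "W_uh", "W_ux", "W_oh", "W_ox", "W_ch", "W_cx")),
                *(rng.normal(size=H) for _ in range(4)),
            )
            x = rng.normal(size=D)
            h0 = rng.normal(size=H)
            c0 = rng.normal(size=H)
            h, c = lstm_unit_step(p, x, h0, c0)
            h_ref, c_ref = scalar_lstm_reference(p, x, h0, c0)
            np.testing.assert_allclose(h, h_ref, atol=1e-5)
            np.testing.assert_allclose(c, c_ref, atol=1e-5)

    def test_gate_bounds_and_state_growth(self, rng):
        for _ in range(5):
            p = LSTMUnitParams(
                *(rng.normal(size=(4, 4)) for _ in range(2 * 4)),
                *(rng.normal(size=4) for _ in range(4)),
            )
            c_prev = rng.normal(size=4) * 3
            h, c = lstm_unit_step(p, rng.normal(size=4), rng.normal(size=4), c_prev)
            assert np.all(np.abs(h) < 1.0)
            assert np.all(np.abs(c) <= np.abs(c_prev) + 1.0 + 1e-12)

    def test_shape_mismatch_rejected(self):
        p = LSTMUnitParams.zeros(3, 2)
        with pytest.raises(ValueError):
            lstm_unit_step(p, [1.0, 2.0, 3.0], np.zeros(3), np.zeros(3))

    def test_network_step_matches_unit_equations(self, rng):
        """The stacked-weight network layer and the per-gate reference
        implement the same update (dual-route check)."""
        from crawlemg.classify import _LSTMLayer
        layer = _LSTMLayer(rng, d_in=5, hidden=7)
        X = rng.normal(size=(1, 1, 5))
        h_net, _ = layer.forward(X)
        p = LSTMUnitParams.from_stacked(layer.Wx, layer.Wh, layer.b)
        h_ref, _ = lstm_unit_step(p, X[0, 0], np.zeros(7), np.zeros(7))
        np.testing.assert_allclose(h_net[0], h_ref, atol=1e-10)


class TestBiLSTM:
    def test_scores_are_probabilities(self, rng):
        ds = _toy_dataset(rng)
        model = train(SMALL_BILSTM, ds, seed=0)
        p = model.predict_scores(ds[:7])
        assert p.shape == (7, 2)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_input_invariant_to_time_reversal(self, rng):
        ds = _toy_dataset(rng)
        model = train(SMALL_BILSTM, ds, seed=0)
        const = EnvelopeCycle(np.ones((200, 6)), "A", "P1", "low")
        flipped = EnvelopeCycle(const.values[::-1].copy(), "A", "P1", "low")
        np.testing.assert_allclose(bilstm_forward(model, const),
                                   bilstm_forward(model, flipped), atol=1e-9)

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        ds = _toy_dataset(rng)
        model = train(SMALL_BILSTM, ds, seed=0)
        assert model.history["final_train_accuracy"] == 100.0
        assert list(model.predict(ds)) == [s.mode for s in ds]

    def test_same_seed_identical_predictions(self, rng):
        ds = _toy_dataset(rng)
        a = train(SMALL_BILSTM, ds, seed=3).predict_scores(ds)
        b = train(SMALL_BILSTM, ds, seed=3).predict_scores(ds)
        np.testing.assert_array_equal(a, b)

    def test_gradients_match_numeric_differentiation(self, rng):
        """Analytic BPTT gradient vs central finite differences on a tiny net."""
        spec = ClassifierSpec(kind="bilstm", hidden_units=3, dense_sizes=(4,),
                              epochs=1, time_steps=5)
        model = BiLSTMClassifier(spec, seed=0)
        ds = _toy_dataset(rng, n_per_class=2, n_points=5, n_channels=2)
        labels = np.array([s.mode for s in ds])
        model.classes_ = np.unique(labels)
        X = np.stack([s.values for s in ds])
        Y = np.eye(2)[np.searchsorted(model.classes_, labels)]
        model._build(2, 2)

        def loss():
            p, *_ = model._forward(X)
            return -np.mean(np.sum(Y * np.log(p + 1e-300), axis=1))

        p, acts, cf, cb = model._forward(X)
        grads = model._backward(p, Y, acts, cf, cb)
        params = model._all_params()
        rng2 = np.random.default_rng(0)
        for param, grad in zip(params, grads):
            flat = param.ravel()
            for idx in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grad.ravel()[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)

    def test_batch_size_is_tenth_of_training_set(self):
        assert ClassifierSpec(kind="bilstm").batch_size(900) == 90
        assert ClassifierSpec(kind="bilstm").batch_size(905) == 91


class TestSklearnClassifiers:
    @pytest.mark.parametrize("kind", ["svm", "knn"])
    def test_separable_toy_perfect(self, rng, kind):
        ds = _toy_dataset(rng)
        model = train(ClassifierSpec(kind=kind), ds, seed=0)
        assert list(predict(model, ds)) == [s.mode for s in ds]

    def test_knn_k1_returns_own_label(self, rng):
        ds = _toy_dataset(rng)
        model = train(ClassifierSpec(kind="knn", n_neighbors=1), ds, seed=0)
        assert list(model.predict(ds)) == [s.mode for s in ds]

    def test_empty_prediction(self, rng):
        model = train(ClassifierSpec(kind="knn"), _toy_dataset(rng), seed=0)
        assert model.predict([]).size == 0

    def test_single_class_rejected(self, rng):
        ds = [s for s in _toy_dataset(rng) if s.mode == "A"]
        with pytest.raises(ValueError, match="2 classes"):
            train(ClassifierSpec(kind="svm"), ds, seed=0)

    @pytest.mark.parametrize("kind", ["svm", "knn"])
    def test_invariant_to_consistent_channel_permutation(self, rng, kind):
        ds = _toy_dataset(rng)
        perm = rng.permutation(6)
        permuted = [EnvelopeCycle(s.values[:, perm], s.mode, s.participant_id,
                                  s.speed) for s in ds]
        a = train(ClassifierSpec(kind=kind), ds, seed=0).predict(ds)
        b = train(ClassifierSpec(kind=kind), permuted, seed=0).predict(permuted)
        np.testing.assert_array_equal(a, b)

    def test_flatten_features_decimation(self, rng):
        ds = _toy_dataset(rng, n_per_class=1, n_points=1000)
        X = flatten_features(ds, 100)
        assert X.shape == (2, 600)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="forest")

    def test_spec_round_trip(self):
        spec = ClassifierSpec(kind="bilstm", hidden_units=8, dense_sizes=(4, 2))
        assert ClassifierSpec.from_dict(spec.to_dict()) == spec
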