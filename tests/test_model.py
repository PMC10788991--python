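"""Architecture census, reference-equation oracles, dropout schemes."""

import numpy as np
import pytest

from nyhagrade import nn
from nyhagrade.model import (
    LSTMWeights,
    ModelConfig,
    NYHAClassifier,
    SEParams,
    apply_dropout_scheme,
    build_model,
    lstm_step_reference,
    se_block_reference,
)


class TestArchitectureCensus:
    def test_cnn_lstm_se_has_twenty_components(self):
        net = build_model(ModelConfig(variant="cnn_lstm_se"))
        assert net.census() == {"conv": 3, "se": 2, "lstm": 10, "gap": 3, "dense": 2}
        assert net.n_layers() == 20

    def test_cnn_has_nine_layers(self):
        net = build_model(ModelConfig(variant="cnn"))
        assert net.census() == {"conv": 3, "pool": 3, "dense": 3}
        assert net.n_layers() == 9

    def test_cnn_lstm_census(self):
        net = build_model(ModelConfig(variant="cnn_lstm"))
        assert net.census() == {"conv": 3, "lstm": 10, "gap": 3, "dense": 2}

    @pytest.mark.parametrize("variant", ["cnn", "cnn_lstm", "cnn_lstm_se"])
    def test_softmax_rows_sum_to_one_on_zero_batch(self, variant):
        cfg = ModelConfig(variant=variant, input_length=200, conv_filters=(4, 6, 8),
                          n_lstm_layers=2, lstm_hidden=8, se_reduction=2)
        net = build_model(cfg)
        probs = nn.softmax(net.forward(np.zeros((3, 200), dtype=np.float32)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_too_short_input_names_the_stage(self):
        with pytest.raises(ValueError, match="conv"):
            build_model(ModelConfig(variant="cnn", input_length=5, pool_size=4))

    def test_forward_is_deterministic_in_eval_mode(self):
        cfg = ModelConfig(variant="cnn_lstm_se", input_length=150,
                          conv_filters=(4, 6, 8), n_lstm_layers=2, lstm_hidden=8,
                          se_reduction=2, dropout_scheme="B", seed=3)
        net = build_model(cfg)
        x = np.random.default_rng(0).normal(size=(4, 150)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))


class TestSEBlockReference:
    def test_zero_weights_halve_the_input(self, rng):
        x = rng.normal(size=(6, 11))
        p = SEParams(fc1_w=np.zeros((3, 6)), fc1_b=np.zeros(3),
                     fc2_w=np.zeros((6, 3)), fc2_b=np.zeros(6))
        np.testing.assert_allclose(se_block_reference(x, p), 0.5 * x, atol=1e-12)

    def test_zero_input_stays_zero(self, rng):
        p = SEParams(fc1_w=rng.normal(size=(3, 6)), fc1_b=rng.normal(size=3),
                     fc2_w=rng.normal(size=(6, 3)), fc2_b=rng.normal(size=6))
        out = se_block_reference(np.zeros((6, 9)), p)
        np.testing.assert_array_equal(out, np.zeros((6, 9)))

    def test_matches_stepwise_composition(self, rng):
        x = rng.normal(size=(8, 15))
        p = SEParams(fc1_w=rng.normal(size=(2, 8)), fc1_b=rng.normal(size=2),
                     fc2_w=rng.normal(size=(8, 2)), fc2_b=rng.normal(size=8))
        squeeze = np.array([x[c].mean() for c in range(8)])
        hidden = np.maximum(p.fc1_w @ squeeze + p.fc1_b, 0)
        w = 1.0 / (1.0 + np.exp(-(p.fc2_w @ hidden + p.fc2_b)))
        expected = np.array([x[c] * w[c] for c in range(8)])
        np.testing.assert_allclose(se_block_reference(x, p), expected, atol=1e-10)

    def test_every_channel_is_scaled_by_weight_in_unit_interval(self, rng):
        x = rng.normal(size=(5, 20)) + 1.0
        p = SEParams(fc1_w=rng.normal(size=(2, 5)), fc1_b=rng.normal(size=2),
                     fc2_w=rng.normal(size=(5, 2)), fc2_b=rng.normal(size=5))
        out = se_block_reference(x, p)
        ratios = out / x
        for c in range(5):
            w = np.unique(np.round(ratios[c], 10))
            assert len(w) == 1 and 0.0 < w[0] < 1.0

    def test_matches_training_layer(self, rng):
        layer = nn.SEBlock1d(10, 2, np.random.default_rng(5))
        x = rng.normal(size=(1, 10, 30)).astype(np.float32)
        p = SEParams(fc1_w=layer.W1.astype(float), fc1_b=layer.b1.astype(float),
                     fc2_w=layer.W2.astype(float), fc2_b=layer.b2.astype(float))
        ref = se_block_reference(x[0].astype(float), p)
        got = layer.forward(x)[0]
        assert np.abs(ref - got).max() < 1e-5


class TestLSTMStepReference:
    def test_zero_weights_analytic_values(self):
        h, c = 3, 3
        w = LSTMWeights(*([np.zeros((h, 2 * h))] * 4), *([np.zeros(h)] * 4))
        c_prev = np.array([1.0, -2.0, 0.5])
        h_t, c_t = lstm_step_reference(np.zeros(h), np.zeros(h), c_prev, w)
        np.testing.assert_allclose(c_t, 0.5 * c_prev, atol=1e-12)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)

    def test_zero_cell_state_with_zero_weights_gives_zero_output(self):
        w = LSTMWeights(*([np.zeros((2, 4))] * 4), *([np.zeros(2)] * 4))
        h_t, c_t = lstm_step_reference(np.zeros(2), np.zeros(2), np.zeros(2), w)
        np.testing.assert_array_equal(h_t, np.zeros(2))
        np.testing.assert_array_equal(c_t, np.zeros(2))

    def test_gates_stay_in_unit_interval(self, rng):
        w = LSTMWeights.random(6, 4, rng, scale=2.0)
        x = rng.normal(size=4)
        h_prev = rng.normal(size=6)
        concat = np.concatenate([h_prev, x])
        for K, Z in ((w.K_f, w.Z_f), (w.K_i, w.Z_i), (w.K_o, w.Z_o)):
            gate = 1.0 / (1.0 + np.exp(-(K @ concat + Z)))
            assert np.all(gate > 0) and np.all(gate < 1)

    def test_dimension_mismatch_raises(self, rng):
        w = LSTMWeights.random(4, 3, rng)
        with pytest.raises(ValueError, match="dimension mismatch"):
            lstm_step_reference(np.zeros(5), np.zeros(4), np.zeros(4), w)

    def test_iterated_reference_matches_training_layer(self, rng):
        layer = nn.LSTM(5, 7, np.random.default_rng(9))
        layer.K[...] = rng.normal(0, 0.4, layer.K.shape).astype(np.float32)
        layer.Z[...] = rng.normal(0, 0.4, layer.Z.shape).astype(np.float32)
        w = LSTMWeights.from_packed(layer.K.astype(float), layer.Z.astype(float))
        x = rng.normal(size=(3, 11, 5)).astype(np.float32)
        got = layer.forward(x, train=False)
        h = np.zeros((3, 7))
        c = np.zeros((3, 7))
        for t in range(11):
            h, c = lstm_step_reference(x[:, t, :], h, c, w)
            assert np.abs(h - got[:, t, :]).max() < 1e-5


class TestDropoutScheme:
    def test_scheme_a_no_dropout(self):
        cfg = apply_dropout_scheme(ModelConfig(), "A")
        assert cfg.lstm_dropout_rates == (0.0, 0.0)

    def test_scheme_b_twenty_percent(self):
        cfg = apply_dropout_scheme(ModelConfig(), "B")
        assert cfg.lstm_dropout_rates == (0.2, 0.2)

    def test_scheme_b_inference_is_deterministic(self):
        cfg = ModelConfig(variant="cnn_lstm", input_length=120, conv_filters=(3, 4, 5),
                          n_lstm_layers=2, lstm_hidden=6, dropout_scheme="B")
        net = build_model(cfg)
        x = np.random.default_rng(2).normal(size=(2, 120)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x, train=False),
                                      net.forward(x, train=False))

    def test_scheme_b_training_actually_drops(self):
        cfg = ModelConfig(variant="cnn_lstm", input_length=120, conv_filters=(3, 4, 5),
                          n_lstm_layers=1, lstm_hidden=16, dropout_scheme="B", seed=1)
        net = build_model(cfg)
        x = np.random.default_rng(2).normal(size=(2, 120)).astype(np.float32)
        a = net.forward(x, train=True)
        b = net.forward(x, train=True)
        assert not np.array_equal(a, b)


class TestEstimatorProtocol:
    def test_clone_and_get_params_roundtrip(self):
        from sklearn.base import clone

        est = NYHAClassifier.reduced(epochs=1, seed=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_shapes_and_determinism(self, rng):
        X = rng.normal(size=(40, 250)).astype(np.float32)
        y = np.repeat([1, 2, 3, 4], 10)
        est = NYHAClassifier.reduced(epochs=1, seed=5)
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (40, 4)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        est2 = NYHAClassifier.reduced(epochs=1, seed=5).fit(X, y)
        np.testing.assert_array_equal(est.predict(X), est2.predict(X))

    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(24, 250)).astype(np.float32)
        y = np.repeat([1, 2, 3, 4], 6)
        est = NYHAClassifier.reduced(epochs=1, seed=2).fit(X, y)
        est.save(tmp_path / "ckpt.npz")
        back = NYHAClassifier.load(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(back.predict_proba(X), est.predict_proba(X),
                                   atol=1e-6)
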