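"""Numerical correctness of the network core: forward references,
finite-difference gradients, and optimization behavior."""
import numpy as np
import pytest

from seizurenet.nn import (
    AvgPool1D,
    BiRNN,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Sequential,
    ShapeError,
    TrainingDivergedError,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def ref_lstm(x_tbc, wx, wh, b):
    """Float64 step-by-step LSTM reference."""
    T, B, _ = x_tbc.shape
    H = wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.empty((T, B, H))
    for t in range(T):
        pre = x_tbc[t].astype(float) @ wx.astype(float) + h @ wh.astype(
            float) + b.astype(float)
        i, f = _sigmoid(pre[:, :H]), _sigmoid(pre[:, H:2 * H])
        g, o = np.tanh(pre[:, 2 * H:3 * H]), _sigmoid(pre[:, 3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        out[t] = h
    return out


def ref_gru(x_tbc, wrz, wn, urz, un, brz, bn):
    """Float64 step-by-step GRU reference (reset-before-candidate)."""
    T, B, _ = x_tbc.shape
    H = un.shape[0]
    h = np.zeros((B, H))
    out = np.empty((T, B, H))
    for t in range(T):
        pre = x_tbc[t].astype(float) @ wrz.astype(float) + h @ urz.astype(
            float) + brz.astype(float)
        r, z = _sigmoid(pre[:, :H]), _sigmoid(pre[:, H:])
        n = np.tanh(x_tbc[t].astype(float) @ wn.astype(float)
                    + (r * h) @ un.astype(float) + bn.astype(float))
        h = z * h + (1 - z) * n
        out[t] = h
    return out


class TestRecurrentForward:
    @pytest.mark.parametrize("kind", ["lstm", "gru"])
    def test_matches_float64_reference(self, kind):
        rng = np.random.default_rng(0)
        layer = BiRNN(3, 5, kind, rng)
        x = rng.standard_normal((2, 40, 3)).astype(np.float32)
        out = layer.forward(x)
        x_tbc = x.transpose(1, 0, 2)
        if kind == "lstm":
            d = layer.fwd
            ref_f = ref_lstm(x_tbc, d.wx, d.wh, d.b)
            d = layer.bwd
            ref_b = ref_lstm(x_tbc[::-1], d.wx, d.wh, d.b)[::-1]
        else:
            d = layer.fwd
            ref_f = ref_gru(x_tbc, d.wrz, d.wn, d.urz, d.un, d.brz, d.bn)
            d = layer.bwd
            ref_b = ref_gru(x_tbc[::-1], d.wrz, d.wn, d.urz, d.un, d.brz,
                            d.bn)[::-1]
        ref = np.concatenate([ref_f, ref_b], axis=2).transpose(1, 0, 2)
        assert np.abs(out - ref).max() < 1e-5


def _loss(model, x, y):
    p = model.forward(x)
    return -float((y * np.log(np.clip(p, 1e-7, 1.0))).sum()) / len(x)


def finite_diff_check(model, x, y, n_samples=6, eps=3e-3, tol=0.03):
    """Compare analytic gradients with central differences.

    Checks a random subsample of coordinates per parameter; tolerance is
    loose enough for float32 arithmetic but catches any structural error.
    """
    p = model.forward(x, training=True)
    model.backward((p - y) / np.float32(len(x)))
    grads = [g.copy() for g in model.grads]
    for pi, (par, ana) in enumerate(zip(model.params, grads)):
        flat, aflat = par.ravel(), ana.ravel()
        idxs = np.random.default_rng(pi).choice(
            flat.size, size=min(n_samples, flat.size), replace=False)
        for i in idxs:
            old = flat[i]
            flat[i] = old + eps
            lp = _loss(model, x, y)
            flat[i] = old - eps
            lm = _loss(model, x, y)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(aflat[i]), 1e-3)
            assert abs(num - aflat[i]) / denom < tol, \
                f"param {pi} index {i}: numeric {num} vs analytic {aflat[i]}"


class TestGradients:
    @pytest.mark.parametrize("kind", ["lstm", "gru"])
    def test_recurrent_stack_gradients(self, kind):
        rng = np.random.default_rng(3)
        model = Sequential([
            BiRNN(1, 4, kind, rng),
            AvgPool1D(2),
            Flatten(),
            Dense(6 * 8, 3, rng, activation="softmax"),
        ])
        x = (rng.standard_normal((3, 12, 1)) * 0.5).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 3)]
        finite_diff_check(model, x, y)

    def test_conv_dense_gradients(self):
        # linear conv activation: keeps finite differences off ReLU kinks
        rng = np.random.default_rng(4)
        model = Sequential([
            Conv1D(1, 3, 2, rng, activation="linear"),
            AvgPool1D(2),
            Flatten(),
            Dense(5 * 3, 4, rng, activation="relu"),
            Dense(4, 2, rng, activation="softmax"),
        ])
        x = (rng.standard_normal((4, 11, 1))).astype(np.float32)
        y = np.eye(2, dtype=np.float32)[rng.integers(0, 2, 4)]
        finite_diff_check(model, x, y)


class TestLayerContracts:
    def test_conv_valid_padding_shrinks_time_axis(self):
        rng = np.random.default_rng(0)
        conv = Conv1D(1, 4, 3, rng)
        assert conv.out_shape((10, 1)) == (8, 4)
        with pytest.raises(ShapeError):
            conv.out_shape((2, 1))

    def test_avgpool_floor_and_backward_shape(self):
        pool = AvgPool1D(2)
        x = np.arange(2 * 5 * 1, dtype=np.float32).reshape(2, 5, 1)
        out = pool.forward(x)
        assert out.shape == (2, 2, 1)
        assert out[0, 0, 0] == pytest.approx(0.5)
        assert pool.backward(np.ones_like(out)).shape == x.shape

    def test_dropout_identity_at_inference_scaled_in_training(self):
        rng = np.random.default_rng(0)
        drop = Dropout(0.5, rng)
        x = np.ones((4, 10, 3), dtype=np.float32)
        assert np.array_equal(drop.forward(x, training=False), x)
        out = drop.forward(x, training=True)
        assert set(np.unique(out)) <= {0.0, 2.0}

    def test_softmax_outputs_on_simplex(self):
        rng = np.random.default_rng(1)
        dense = Dense(7, 4, rng, activation="softmax")
        p = dense.forward(rng.standard_normal((9, 7)).astype(np.float32))
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.standard_normal((n, 30, 1)).astype(np.float32)
        y_cls = (rng.random(n) < 0.5).astype(int)
        x[y_cls == 1] += 3.0
        y = np.eye(2, dtype=np.float32)[y_cls]
        model = Sequential([
            Conv1D(1, 4, 2, rng),
            AvgPool1D(2),
            Flatten(),
            Dense(14 * 4, 8, rng),
            Dense(8, 2, rng, activation="softmax"),
        ])
        history = model.fit(x, y, epochs=60, batch_size=16,
                            rng=np.random.default_rng(0))
        assert history[-1] < history[0] * 0.5
        assert (model.predict(x) == y_cls).mean() > 0.9

    def test_divergence_raises(self):
        rng = np.random.default_rng(6)
        model = Sequential([
            Flatten(),
            Dense(8, 2, rng, activation="softmax"),
        ])
        x = np.full((4, 8, 1), 1e30, dtype=np.float32)
        y = np.eye(2, dtype=np.float32)[[0, 1, 0, 1]]
        with pytest.raises(TrainingDivergedError):
            model.fit(x, y, epochs=5, batch_size=4,
                      rng=np.random.default_rng(0), lr=1e3)

    def test_identical_seeds_identical_initial_weights(self):
        from seizurenet.architecture import build_model, get_config
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg, _ = get_config(6, "A-E", "lstm")
        a = build_model(cfg, 178, seed=12)
        b = build_model(cfg, 178, seed=12)
        assert all(np.array_equal(pa, pb)
                   for pa, pb in zip(a.params, b.params))
        assert a.count_params() == b.count_params()
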