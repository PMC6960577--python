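import numpy as np
import pytest

from affectflight.net import (
    MLPModel,
    NetworkSpec,
    _forward_full,
    forward,
    gradients,
    init_network,
    load_model,
    mean_error_energy,
    predict,
    save_model,
    train,
)


def _spec(**kw):
    base = dict(n_input=3, hidden=(2,), n_output=2, learning_rate=0.3,
                momentum=0.0, epochs=10, seed=1)
    base.update(kw)
    return NetworkSpec(**base)


class TestInit:
    def test_shapes_chain(self):
        spec = NetworkSpec(n_input=50, hidden=(83, 83), n_output=5)
        m = init_network(spec)
        assert [w.shape for w in m.weights] == [(83, 50), (83, 83), (5, 83)]
        assert all(np.all(b == 0) for b in m.biases)

    def test_seed_determinism(self):
        a = init_network(_spec(seed=9))
        b = init_network(_spec(seed=9))
        c = init_network(_spec(seed=10))
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
        assert any(not np.array_equal(x, y) for x, y in zip(a.weights, c.weights))


class TestForward:
    def test_zero_weights_sigmoid_gives_half(self):
        m = init_network(_spec())
        for w in m.weights:
            w[:] = 0.0
        out = forward(m, np.zeros(3))
        assert np.allclose(out, 0.5)

    def test_induced_local_field_arithmetic(self):
        spec = NetworkSpec(n_input=2, hidden=(1,), n_output=1,
                           activation="relu", epochs=1)
        m = init_network(spec)
        m.weights[0][:] = np.array([[1.0, 2.0]])
        m.biases[0][:] = 0.0
        m.weights[1][:] = np.array([[1.0]])
        vs, _ = _forward_full(m, np.array([[3.0, 4.0]]))
        assert vs[0][0, 0] == pytest.approx(11.0)  # 1·3 + 2·4

    def test_softmax_outputs_sum_to_one(self, rng):
        spec = _spec(output_mode="classification")
        m = init_network(spec)
        out = forward(m, rng.normal(size=(20, 3)))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_width_mismatch_rejected(self):
        m = init_network(_spec())
        with pytest.raises(ValueError, match="width"):
            forward(m, np.zeros(5))


def _finite_diff_grads(model, X, D, eps=1e-6):
    gw = []
    for W in model.weights:
        g = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            orig = W[idx]
            W[idx] = orig + eps
            lp = mean_error_energy(model, X, D)
            W[idx] = orig - eps
            lm = mean_error_energy(model, X, D)
            W[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        gw.append(g)
    gb = []
    for b in model.biases:
        g = np.zeros_like(b)
        for idx in np.ndindex(b.shape):
            orig = b[idx]
            b[idx] = orig + eps
            lp = mean_error_energy(model, X, D)
            b[idx] = orig - eps
            lm = mean_error_energy(model, X, D)
            b[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        gb.append(g)
    return gw, gb


class TestGradients:
    @pytest.mark.parametrize("activation", ["sigmoid", "relu"])
    @pytest.mark.parametrize("output_mode", ["regression", "classification"])
    def test_backprop_matches_central_differences(self, activation, output_mode, rng):
        """Analytic gradients on a 3-2-2 net vs finite differences."""
        spec = _spec(activation=activation, output_mode=output_mode, seed=4)
        m = init_network(spec)
        X = rng.normal(size=(5, 3))
        D = rng.uniform(0.1, 0.9, size=(5, 2))
        aw, ab = gradients(m, X, D)
        nw, nb = _finite_diff_grads(m, X, D)
        for a, n in zip(aw + ab, nw + nb):
            scale = np.maximum(np.abs(n), 1e-4)
            assert np.max(np.abs(a - n) / scale) < 1e-5

    def test_first_order_loss_decrease(self, rng):
        """One sgd step with α=0, tiny η changes loss by ≈ −η‖∇‖²."""
        spec = _spec(momentum=0.0, learning_rate=1e-4, seed=2)
        m = init_network(spec)
        X = rng.normal(size=(8, 3))
        D = rng.uniform(0.2, 0.8, size=(8, 2))
        gw, gb = gradients(m, X, D)
        gnorm2 = sum(float(np.sum(g**2)) for g in gw + gb)
        before = mean_error_energy(m, X, D)
        train(m, X, D, epochs=1)
        after = mean_error_energy(m, X, D)
        assert (before - after) == pytest.approx(1e-4 * gnorm2, rel=0.1)


class TestTrain:
    def test_zero_error_is_fixed_point(self):
        m = init_network(_spec(momentum=0.0))
        X = np.random.default_rng(0).normal(size=(4, 3))
        D = forward(m, X)  # targets equal current outputs → ε = 0
        w_before = [w.copy() for w in m.weights]
        train(m, X, np.clip(D, 0, 1), epochs=3)
        for a, b in zip(m.weights, w_before):
            assert np.allclose(a, b, atol=1e-12)

    def test_xor_style_convergence(self):
        """Small sigmoid+sgd net drives a nonlinearly separable 2-output
        toy problem below RMSE 0.1 within the default epoch budget."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        D = np.column_stack([[0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        spec = NetworkSpec(n_input=2, hidden=(4,), n_output=2,
                           activation="sigmoid", optimizer="sgd",
                           learning_rate=0.9, momentum=0.9, epochs=6000,
                           batch_mode="online", seed=0)
        m = train(init_network(spec), X, D)
        out = predict(m, X)
        assert np.sqrt(np.mean((out - D) ** 2)) < 0.1

    def test_loss_decreases_on_separable_data(self, rng):
        X = rng.normal(size=(30, 3))
        D = 1 / (1 + np.exp(-X @ rng.normal(size=(3, 2))))
        spec = _spec(optimizer="adam", learning_rate=0.01, epochs=200)
        m = train(init_network(spec), X, D)
        first = np.mean(m.loss_trace[:20])
        last = np.mean(m.loss_trace[-20:])
        assert last <= first

    def test_targets_outside_unit_interval_rejected(self):
        m = init_network(_spec())
        with pytest.raises(ValueError, match="targets"):
            train(m, np.zeros((2, 3)), np.array([[0.5, 1.5]] * 2))


class TestPredict:
    def test_deterministic_and_bounded(self, rng):
        m = init_network(_spec())
        X = rng.normal(size=(10, 3))
        a = predict(m, X)
        b = predict(m, X)
        assert np.array_equal(a, b)
        assert np.all((a > 0) & (a < 1))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        m = init_network(_spec(seed=8))
        X = rng.normal(size=(6, 3))
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        assert np.allclose(predict(m, X), predict(m2, X))
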