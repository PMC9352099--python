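"""Network arithmetic: shape trace, softmax, losses, gradients, training."""

import numpy as np
import pytest

from dermopipe import scnn
from dermopipe.scnn import ModelSpec, TrainConfig, forward_shapes, loss, softmax


def _side(trace, name):
    return dict((layer, side) for layer, side, _ in trace)[name]


def test_shape_trace_matches_published_dimensions():
    trace = forward_shapes(ModelSpec())
    assert _side(trace, "conv1") == 222
    assert _side(trace, "pool1") == 111
    assert _side(trace, "conv3") == 52
    assert _side(trace, "pool4") == 12
    flat = [c for layer, _, c in trace if layer == "flatten"][0]
    assert flat == 12 * 12 * 64


def test_shape_trace_tiny_input_and_floor_pooling():
    trace = forward_shapes(ModelSpec(input_shape=(4, 4, 1), conv_filters=(2,)))
    assert _side(trace, "conv1") == 2 and _side(trace, "pool1") == 1
    for n in (9, 15, 31):
        tr = forward_shapes(ModelSpec(input_shape=(n, n, 1), conv_filters=(2,)))
        assert _side(tr, "pool1") == (n - 2) // 2


def test_shape_underflow_rejected():
    with pytest.raises(ValueError):
        scnn.build_model(ModelSpec(input_shape=(16, 16, 3)))


def test_softmax_normalization_and_shift_invariance():
    rng = np.random.default_rng(0)
    logits = rng.normal(0, 3, (20, 2))
    p = softmax(logits)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(softmax(logits + 7.3), p, atol=1e-12)
    assert np.allclose(softmax(np.zeros((1, 2)))[0], [0.5, 0.5])
    big = softmax(np.array([[50.0, -50.0]]))[0]
    assert big[0] > 0.999999


def test_loss_registry_values():
    assert loss("binary_ce", [1.0], [1.0 - 1e-9]) == pytest.approx(0.0, abs=1e-6)
    assert loss("binary_ce", [1.0], [0.5]) == pytest.approx(-np.log(0.5))
    assert loss("mse", [1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        loss("hinge", [1.0], [0.5])


def test_focal_gamma_zero_alpha_half_is_half_bce():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50).astype(float)
    p = rng.uniform(0.05, 0.95, 50)
    fl = loss("focal", y, p, focal_alpha=0.5, focal_gamma=0.0)
    bce = loss("binary_ce", y, p)
    assert fl == pytest.approx(0.5 * bce, rel=1e-9)


def test_parameter_counts_follow_conv_formula():
    spec = ModelSpec.reduced()
    model = scnn.build_model(spec)
    counts = scnn.count_parameters(model)
    c_in = 3
    for i, m in enumerate(spec.conv_filters, start=1):
        assert counts[f"conv{i}"] == 3 * 3 * c_in * m + m  # K^2 * N * M + biases
        c_in = m


def _numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        hi = f()
        arr[idx] = orig - eps
        lo = f()
        arr[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def test_backprop_matches_numeric_gradients():
    """Analytic conv/dense gradients agree with central differences."""
    spec = ModelSpec(input_shape=(10, 10, 2), conv_filters=(3,), dense_units=5, dropout=0.0)
    model = scnn.build_model(spec, seed=0)
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, (4, 10, 10, 2))
    y = np.array([0, 1, 1, 0])
    cfg = TrainConfig(loss="categorical_ce", epochs=1)

    def loss_value():
        logits = model.forward(x, train=False)
        val, _ = scnn._loss_and_dlogits(model, logits, y, cfg)
        return val

    logits = model.forward(x, train=False)
    _, dlogits = scnn._loss_and_dlogits(model, logits, y, cfg)
    model.backward(dlogits)

    for layer, pname in [(model.convs[0], "w"), (model.convs[0], "b"),
                         (model.dense2, "w"), (model.dense1, "b")]:
        analytic = layer.grads()[pname]
        # probe a handful of coordinates to keep the check fast
        flat = analytic.ravel()
        probe = np.linspace(0, flat.size - 1, 6, dtype=int)
        param = layer.params()[pname]
        for k in probe:
            idx = np.unravel_index(k, param.shape)
            orig = param[idx]
            eps = 1e-6
            param[idx] = orig + eps
            hi = loss_value()
            param[idx] = orig - eps
            lo = loss_value()
            param[idx] = orig
            num = (hi - lo) / (2 * eps)
            assert num == pytest.approx(flat[k], rel=1e-4, abs=1e-7)


def test_zero_epochs_returns_untrained_model():
    spec = ModelSpec(input_shape=(10, 10, 1), conv_filters=(2,), dense_units=4)
    model = scnn.build_model(spec, seed=1)
    before = model.get_weights()
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 10, 10, 1))
    y = np.array([0, 1, 0, 1, 0, 1])
    out = scnn.train(model, x, y, x, y, TrainConfig(epochs=0))
    assert out.history["train_loss"] == []
    for a, b in zip(before, out.get_weights()):
        for k in a:
            assert np.array_equal(a[k], b[k])


def test_training_deterministic_under_seed():
    spec = ModelSpec(input_shape=(10, 10, 1), conv_filters=(2,), dense_units=4)
    rng = np.random.default_rng(4)
    x = rng.normal(size=(12, 10, 10, 1))
    y = (x.mean(axis=(1, 2, 3)) > 0).astype(int)
    cfg = TrainConfig(epochs=3, batch_size=4, seed=7)
    runs = []
    for _ in range(2):
        model = scnn.build_model(spec, seed=7)
        model = scnn.train(model, x, y, x, y, cfg)
        runs.append(model.history["train_loss"][-1])
    assert runs[0] == runs[1]


def test_predict_probabilities_and_label_mapping():
    spec = ModelSpec(input_shape=(10, 10, 1), conv_filters=(2,), dense_units=4)
    rng = np.random.default_rng(6)
    x = rng.normal(size=(30, 10, 10, 1))
    means = []
    for seed in range(20):
        model = scnn.build_model(spec, seed=seed)
        probs, labels = scnn.predict(model, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(np.unique(labels)) <= {0, 1}
        means.append(probs[:, 1].mean())
    # untrained heads are near-uniform on average over weight draws
    assert abs(np.mean(means) - 0.5) < 0.2


def test_best_epoch_minimizes_validation_loss(reduced_training_run):
    model = reduced_training_run["model"]
    losses = model.history["val_loss"]
    assert model.best_epoch == int(np.argmin(losses))
    assert len(losses) <= 20


def test_training_loss_trends_down_early(reduced_training_run):
    tl = reduced_training_run["model"].history["train_loss"]
    first = np.mean(tl[:3])
    later = np.mean(tl[7:10])
    assert later < first
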