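"""SCNN_12: a shallow convolutional network for benign/malignant classification.

The stack is 4 blocks of (unpadded stride-1 3x3 convolution + ReLU + 2x2
stride-2 max pooling) with 16/32/32/64 filters, then flatten, a 1024-unit
ReLU dense layer with 0.5 dropout, and a 2-unit output read through softmax
(0 = benign, 1 = malignant).  Counting the convolutions, poolings, flatten,
the two dense layers and the softmax gives the "12 weighted layers" depth
the name refers to.

The network, its losses (binary/categorical cross-entropy, MSE, KL
divergence, focal) and the Adam/Nadam/Adamax optimizers are implemented
directly in NumPy: forward/backward passes are exact analytic gradients,
shapes follow valid convolution (n -> n-2) and floor-halving pooling.
A reduced profile (64x64 input, filters divided by 4, 256-unit dense) keeps
desk-scale experiments fast; the full 224x224 profile is the default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Model",
    "build_model",
    "forward_shapes",
    "softmax",
    "loss",
    "LOSSES",
    "train",
    "predict",
    "count_parameters",
]

EPS = 1e-7


@dataclass(frozen=True)
class ModelSpec:
    input_shape: tuple[int, int, int] = (224, 224, 3)
    conv_filters: tuple[int, ...] = (16, 32, 32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 1024
    dropout: float = 0.5
    n_classes: int = 2
    output_activation: str = "softmax"  # or "sigmoid" (1 output unit)

    @staticmethod
    def reduced() -> "ModelSpec":
        """Desk-scale profile: 64x64 input, filters / 4, smaller dense head."""
        return ModelSpec(input_shape=(64, 64, 3), conv_filters=(4, 8, 8, 16), dense_units=256)


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # adam | nadam | adamax
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 200
    loss: str = "categorical_ce"
    output_activation: str = "softmax"
    weight_decay: float = 0.0001
    momentum: float = 0.9  # recorded; the adaptive optimizers use beta1=0.9 instead
    focal_alpha: float = 0.5
    focal_gamma: float = 2.0
    seed: int = 0


def forward_shapes(spec: ModelSpec) -> list[tuple[str, int, int]]:
    """Spatial-side trace (layer, side, channels) through the conv/pool stack.

    Valid convolution maps n -> n - (k - 1); 2x2 pooling maps n -> floor(n/2).
    """
    side = spec.input_shape[0]
    channels = spec.input_shape[2]
    trace: list[tuple[str, int, int]] = [("input", side, channels)]
    for i, filters in enumerate(spec.conv_filters, start=1):
        side = side - (spec.kernel_size - 1)
        if side < 1:
            raise ValueError("spatial size underflow in the convolution stack")
        channels = filters
        trace.append((f"conv{i}", side, channels))
        side = side // spec.pool_size
        if side < 1:
            raise ValueError("spatial size underflow in the pooling stack")
        trace.append((f"pool{i}", side, channels))
    trace.append(("flatten", 1, side * side * channels))
    trace.append(("dense1", 1, spec.dense_units))
    n_out = 1 if spec.output_activation == "sigmoid" else spec.n_classes
    trace.append(("dense2", 1, n_out))
    return trace


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# losses: each entry returns (scalar value, dL/dp elementwise)


def _bce(y: np.ndarray, p: np.ndarray):
    p = np.clip(p, EPS, 1 - EPS)
    val = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    grad = (-(y / p) + (1 - y) / (1 - p)) / p.size
    return val, grad


def _cce(y: np.ndarray, p: np.ndarray):
    p = np.clip(p, EPS, 1 - EPS)
    n = y.shape[0]
    val = -np.sum(y * np.log(p)) / n
    grad = -(y / p) / n
    return val, grad


def _mse_loss(y: np.ndarray, p: np.ndarray):
    val = np.mean((y - p) ** 2)
    grad = 2 * (p - y) / p.size
    return val, grad


def _kld(y: np.ndarray, p: np.ndarray):
    p = np.clip(p, EPS, 1 - EPS)
    yc = np.clip(y, EPS, 1)
    n = y.shape[0]
    val = np.sum(y * np.log(yc / p)) / n
    grad = -(y / p) / n
    return val, grad


def _focal(y: np.ndarray, p: np.ndarray, alpha: float = 0.5, gamma: float = 2.0):
    """Focal loss: down-weights easy examples; gamma=0, alpha=0.5 halves the BCE."""
    p = np.clip(p, EPS, 1 - EPS)
    pos = -alpha * (1 - p) ** gamma * y * np.log(p)
    neg = -(1 - alpha) * p**gamma * (1 - y) * np.log(1 - p)
    val = np.mean(pos + neg)
    dpos = -alpha * y * ((1 - p) ** gamma / p - gamma * (1 - p) ** (gamma - 1) * np.log(p))
    dneg = -(1 - alpha) * (1 - y) * (
        gamma * p ** (gamma - 1) * np.log(1 - p) - p**gamma / (1 - p)
    )
    grad = (dpos + dneg) / p.size
    return val, grad


LOSSES = {
    "binary_ce": _bce,
    "categorical_ce": _cce,
    "mse": _mse_loss,
    "kld": _kld,
    "focal": _focal,
}


def loss(
    name: str,
    y_true: np.ndarray,
    p_pred: np.ndarray,
    focal_alpha: float = 0.5,
    focal_gamma: float = 2.0,
) -> float:
    """Scalar loss from the registry; probabilities are epsilon-clamped."""
    if name not in LOSSES:
        raise ValueError(f"unknown loss: {name!r}")
    y_true = np.asarray(y_true, dtype=np.float64)
    p_pred = np.asarray(p_pred, dtype=np.float64)
    if name == "focal":
        return float(_focal(y_true, p_pred, focal_alpha, focal_gamma)[0])
    return float(LOSSES[name](y_true, p_pred)[0])


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """Valid stride-1 KxK convolution, implemented by kernel-offset shifts."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = rng.normal(0.0, scale, size=(k, k, c_in, c_out)).astype(np.float64)
        self.b = np.zeros(c_out, dtype=np.float64)
        self.k = k

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w_, _ = x.shape
        ho, wo = h - k + 1, w_ - k + 1
        out = np.broadcast_to(self.b, (n, ho, wo, self.w.shape[3])).copy()
        for di in range(k):
            for dj in range(k):
                out += np.tensordot(x[:, di : di + ho, dj : dj + wo, :], self.w[di, dj], axes=1)
        self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        x = self._x
        n, h, w_, _ = x.shape
        ho, wo = h - k + 1, w_ - k + 1
        self.dw = np.empty_like(self.w)
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                patch = x[:, di : di + ho, dj : dj + wo, :]
                self.dw[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, di : di + ho, dj : dj + wo, :] += np.tensordot(
                    dout, self.w[di, dj].T, axes=1
                )
        self.db = dout.sum(axis=(0, 1, 2))
        return dx

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class _MaxPool:
    """2x2 stride-2 max pooling; odd trailing rows/cols are dropped (floor)."""

    def forward(self, x):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        cropped = x[:, : 2 * ho, : 2 * wo, :]
        windows = (
            cropped.reshape(n, ho, 2, wo, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, ho, wo, 4, c)
        )
        self._idx = windows.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(windows, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._shape
        ho, wo = h // 2, w // 2
        dwin = np.zeros((n, ho, wo, 4, c), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, : 2 * ho, : 2 * wo, :] = (
            dwin.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * ho, 2 * wo, c)
        )
        return dx


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float64)
        self.b = np.zeros(n_out, dtype=np.float64)

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Model:
    """The layer stack plus training history; weights live inside the layers."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel_size
        self.convs: list[_Conv] = []
        self.relus: list[_ReLU] = []
        self.pools: list[_MaxPool] = []
        c_in = spec.input_shape[2]
        for f in spec.conv_filters:
            self.convs.append(_Conv(k, c_in, f, rng))
            self.relus.append(_ReLU())
            self.pools.append(_MaxPool())
            c_in = f
        trace = forward_shapes(spec)
        flat = trace[-3][2]
        self.dense1 = _Dense(flat, spec.dense_units, rng)
        self.relu_d = _ReLU()
        self.dropout = _Dropout(spec.dropout)
        n_out = 1 if spec.output_activation == "sigmoid" else spec.n_classes
        self.dense2 = _Dense(spec.dense_units, n_out, rng)
        self.flatten = _Flatten()
        self.history: dict[str, list[float]] = {
            "train_loss": [],
            "train_acc": [],
            "val_loss": [],
            "val_acc": [],
        }
        self.best_epoch: int | None = None

    # -- plumbing ----------------------------------------------------------
    def _param_layers(self):
        return [*self.convs, self.dense1, self.dense2]

    def get_weights(self):
        return [copy.deepcopy(layer.params()) for layer in self._param_layers()]

    def set_weights(self, weights):
        for layer, stored in zip(self._param_layers(), weights):
            for name, arr in stored.items():
                getattr(layer, name)[...] = arr

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch of (N, H, W, C) float inputs."""
        h = x
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        h = self.flatten.forward(h)
        h = self.relu_d.forward(self.dense1.forward(h))
        h = self.dropout.forward(h, train, rng)
        return self.dense2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.dense1.backward(self.relu_d.backward(d))
        d = self.flatten.backward(d)
        for conv, relu, pool in zip(reversed(self.convs), reversed(self.relus), reversed(self.pools)):
            d = conv.backward(relu.backward(pool.backward(d)))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = _as_float(x)
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            if self.spec.output_activation == "sigmoid":
                p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
                outs.append(np.stack([1 - p1, p1], axis=1))
            else:
                outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> Model:
    """Construct the (untrained) layer stack; raises on spatial underflow."""
    spec = spec or ModelSpec()
    forward_shapes(spec)  # validates
    return Model(spec, seed=seed)


def count_parameters(model: Model) -> dict[str, int]:
    """Per-layer parameter counts (conv layer: K^2 * N * M weights + M biases)."""
    counts: dict[str, int] = {}
    for i, conv in enumerate(model.convs, start=1):
        counts[f"conv{i}"] = conv.w.size + conv.b.size
    counts["dense1"] = model.dense1.w.size + model.dense1.b.size
    counts["dense2"] = model.dense2.w.size + model.dense2.b.size
    return counts


# ---------------------------------------------------------------------------
# optimizers


class _AdamFamily:
    def __init__(self, variant: str, lr: float, weight_decay: float = 0.0):
        if variant not in ("adam", "nadam", "adamax"):
            raise ValueError(f"unknown optimizer: {variant!r}")
        self.variant = variant
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2 = 0.9, 0.999
        self.eps = 1e-8
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.wd:
                g = g + self.wd * p  # classical L2 regularization
            m = self.m.setdefault(i, np.zeros_like(p))
            v = self.v.setdefault(i, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            if self.variant == "adamax":
                v[...] = np.maximum(b2 * v, np.abs(g))
                p -= self.lr / (1 - b1**self.t) * m / (v + self.eps)
                continue
            v[...] = b2 * v + (1 - b2) * g * g
            vhat = v / (1 - b2**self.t)
            if self.variant == "nadam":
                mhat = (b1 * m / (1 - b1 ** (self.t + 1))) + ((1 - b1) * g / (1 - b1**self.t))
            else:
                mhat = m / (1 - b1**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training


def _as_float(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype == np.uint8:
        return x.astype(np.float64) / 255.0
    return x.astype(np.float64)


def _one_hot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y), n), dtype=np.float64)
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


def _targets_and_probs(model: Model, logits: np.ndarray, y: np.ndarray):
    if model.spec.output_activation == "sigmoid":
        p = 1.0 / (1.0 + np.exp(-logits))
        t = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    else:
        p = softmax(logits)
        t = _one_hot(y, model.spec.n_classes)
    return t, p


def _loss_and_dlogits(model: Model, logits: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    t, p = _targets_and_probs(model, logits, y)
    fn = LOSSES[cfg.loss]
    if cfg.loss == "focal":
        val, dp = fn(t, p, cfg.focal_alpha, cfg.focal_gamma)
    else:
        val, dp = fn(t, p)
    if model.spec.output_activation == "sigmoid":
        dlogits = dp * p * (1 - p)
    else:
        # chain through the softmax Jacobian
        dot = np.sum(dp * p, axis=1, keepdims=True)
        dlogits = p * (dp - dot)
    return float(val), dlogits


def _evaluate(model: Model, x: np.ndarray, y: np.ndarray, cfg: TrainConfig, batch: int = 64):
    losses, correct = [], 0
    x = _as_float(x)
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch], train=False)
        val, _ = _loss_and_dlogits(model, logits, y[i : i + batch], cfg)
        losses.append(val * len(logits))
        t, p = _targets_and_probs(model, logits, y[i : i + batch])
        if model.spec.output_activation == "sigmoid":
            pred = (p[:, 0] >= 0.5).astype(int)
        else:
            pred = p.argmax(axis=1)
        correct += int((pred == np.asarray(y[i : i + batch], dtype=int)).sum())
    return sum(losses) / len(x), correct / len(x)


def train(
    model: Model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> Model:
    """Seeded mini-batch training; keeps the weights of the epoch with the
    minimum validation loss.  Raises on divergence (non-finite loss)."""
    cfg = cfg or TrainConfig()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if cfg.loss not in LOSSES:
        raise ValueError(f"unknown loss: {cfg.loss!r}")
    if model.spec.output_activation != cfg.output_activation:
        model = build_model(replace(model.spec, output_activation=cfg.output_activation), cfg.seed)
    if cfg.epochs == 0:
        return model

    rng = np.random.default_rng(cfg.seed)
    x_train = _as_float(x_train)
    y_train = np.asarray(y_train, dtype=int)
    opt = _AdamFamily(cfg.optimizer, cfg.learning_rate, cfg.weight_decay)
    best_loss, best_weights = np.inf, None

    param_refs: list[np.ndarray] = []
    for layer in model._param_layers():
        param_refs.extend(layer.params().values())

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True, rng=rng)
            val, dlogits = _loss_and_dlogits(model, logits, yb, cfg)
            if not np.isfinite(val):
                raise RuntimeError(f"training diverged (loss={val}) at epoch {epoch}")
            model.backward(dlogits)
            grads: list[np.ndarray] = []
            for layer in model._param_layers():
                grads.extend(layer.grads().values())
            opt.step(param_refs, grads)
            epoch_loss += val * len(xb)
            t, p = _targets_and_probs(model, logits, yb)
            pred = (p[:, 0] >= 0.5).astype(int) if p.shape[1] == 1 else p.argmax(axis=1)
            epoch_correct += int((pred == yb).sum())
        val_loss, val_acc = _evaluate(model, x_val, y_val, cfg)
        model.history["train_loss"].append(epoch_loss / len(x_train))
        model.history["train_acc"].append(epoch_correct / len(x_train))
        model.history["val_loss"].append(val_loss)
        model.history["val_acc"].append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            model.best_epoch = epoch
    if best_weights is not None:
        model.set_weights(best_weights)
    return model


def predict(model: Model, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (summing to 1) and argmax labels; ties go to 0."""
    probs = model.predict_proba(images)
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return probs, labels
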