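"""1D convolutional network for spectra, implemented in numpy.

The discriminant model at the core of this package: a LeNet-style 1D CNN
taking a preprocessed spectrum (default 454 points) through two
convolution + max-pooling stages, a flatten, a 100-unit fully connected
layer and a softmax output over the five maturity levels.

A convolutional unit computes ``h = f(W·x_window + b)`` — a locally
connected, weight-shared affine map followed by a nonlinearity (ReLU here,
preceded by batch normalization).  A pooling unit computes
``f(beta * max(window) + bias)`` with the multiplicative/additive pooling
biases defaulting to the identity (1, 0).  Valid padding throughout, so a
convolution of kernel k and stride s maps length L to
``floor((L - k)/s) + 1``, and likewise for pooling.

Everything — im2col convolution, batch normalization with moving inference
statistics, max pooling, dense layers, softmax cross-entropy, Adam, and the
full backward pass — is implemented here on numpy arrays; a fixed seed makes
initialization and mini-batch shuffling, and hence the trained model,
bit-reproducible.

``cnn_output_shapes`` propagates shapes symbolically without allocating
weights, and is the oracle the runtime network is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ArchitectureError, TrainingError
from .base import BaseClassifier, check_Xy, one_hot

__all__ = [
    "ConvLayerSpec",
    "PoolLayerSpec",
    "GlobalMaxPoolSpec",
    "CNNArchitecture",
    "TrainConfig",
    "cnn_output_shapes",
    "default_architecture",
    "CNNClassifier",
]


# --------------------------------------------------------------------------
# architecture specification (symbolic)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    """Valid-padding 1D convolution; conv -> batch norm -> ReLU."""

    n_filters: int
    kernel_size: int
    stride: int = 1
    padding: str = "valid"
    activation: str = "relu"
    batch_norm: bool = True

    def out_length(self, L: int) -> int:
        return (L - self.kernel_size) // self.stride + 1


@dataclass(frozen=True)
class PoolLayerSpec:
    """Max pooling with optional multiplicative/additive biases (default identity)."""

    pool_size: int
    stride: int
    reducer: str = "max"
    beta: float = 1.0
    bias: float = 0.0

    def out_length(self, L: int) -> int:
        return (L - self.pool_size) // self.stride + 1


@dataclass(frozen=True)
class GlobalMaxPoolSpec:
    """Whole-map max pooling, collapsing each feature map to one value."""


@dataclass
class CNNArchitecture:
    input_length: int = 454
    n_classes: int = 5
    features: list = field(default_factory=list)  # Conv/Pool/GlobalMaxPool specs
    dense_units: tuple[int, ...] = (100,)


def default_architecture(kernel_size: int = 5, input_length: int = 454,
                         n_classes: int = 5) -> CNNArchitecture:
    """The published two-stage architecture.

    With ``kernel_size=5`` the layer lengths are 450, 225, 221, 221 and the
    flatten width is 221 x 64 = 14144; ``kernel_size=13`` (the tuned value)
    gives 442, 221, 209 and flatten 13376.  Both are first-class configs.
    """
    return CNNArchitecture(
        input_length=input_length,
        n_classes=n_classes,
        features=[
            ConvLayerSpec(n_filters=128, kernel_size=kernel_size, stride=1),
            PoolLayerSpec(pool_size=2, stride=2),
            ConvLayerSpec(n_filters=64, kernel_size=kernel_size, stride=1),
            PoolLayerSpec(pool_size=1, stride=1),
        ],
        dense_units=(100,),
    )


def cnn_output_shapes(arch: CNNArchitecture) -> list[tuple[str, tuple[int, ...]]]:
    """Symbolic shape propagation; no weights are allocated.

    Returns ``[(layer_name, shape), ...]`` where feature-stage shapes are
    ``(length, channels)`` and dense-stage shapes are ``(width,)``.  Raises
    :class:`ArchitectureError` naming the first layer whose output length
    would be non-positive.
    """
    if arch.input_length < 1:
        raise ArchitectureError(f"input length must be positive, got {arch.input_length}")
    shapes: list[tuple[str, tuple[int, ...]]] = [("input", (arch.input_length, 1))]
    L, C = arch.input_length, 1
    conv_i = pool_i = 0
    for spec in arch.features:
        if isinstance(spec, ConvLayerSpec):
            conv_i += 1
            name = f"conv{conv_i}"
            if spec.kernel_size > L:
                raise ArchitectureError(
                    f"{name}: kernel {spec.kernel_size} exceeds input length {L}"
                )
            L, C = spec.out_length(L), spec.n_filters
        elif isinstance(spec, PoolLayerSpec):
            pool_i += 1
            name = f"pool{pool_i}"
            if spec.pool_size > L:
                raise ArchitectureError(
                    f"{name}: pool size {spec.pool_size} exceeds input length {L}"
                )
            L = spec.out_length(L)
        elif isinstance(spec, GlobalMaxPoolSpec):
            pool_i += 1
            name = f"global_max_pool{pool_i}"
            L = 1
        else:
            raise ArchitectureError(f"unknown layer spec {spec!r}")
        if L < 1:
            raise ArchitectureError(f"{name}: output length {L} is not positive")
        shapes.append((name, (L, C)))
    width = L * C
    shapes.append(("flatten", (width,)))
    for i, units in enumerate(arch.dense_units, start=1):
        if units < 1:
            raise ArchitectureError(f"dense{i}: width {units} is not positive")
        shapes.append((f"dense{i}", (units,)))
    shapes.append(("output", (arch.n_classes,)))
    return shapes


def flatten_width(arch: CNNArchitecture) -> int:
    """Width of the flattened feature vector for this architecture."""
    return next(s[0] for name, s in cnn_output_shapes(arch) if name == "flatten")


# --------------------------------------------------------------------------
# runtime layers (channels-last: activations are (N, L, C))
# --------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv1D(_Layer):
    def __init__(self, spec: ConvLayerSpec, in_channels: int, rng: np.random.Generator):
        k, f = spec.kernel_size, spec.n_filters
        fan_in = in_channels * k
        fan_out = f * k
        std = np.sqrt(2.0 / (fan_in + fan_out))  # Xavier normal
        self.W = rng.normal(0.0, std, size=(in_channels * k, f))
        self.b = np.zeros(f)
        self.k, self.stride = k, spec.stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._in_shape = x.shape
        win = sliding_window_view(x, self.k, axis=1)[:, :: self.stride]  # (N,Lo,C,k)
        N, Lo = win.shape[0], win.shape[1]
        self._cols = win.reshape(N, Lo, -1)
        return self._cols @ self.W + self.b

    def backward(self, dy):
        N, Lo, F = dy.shape
        cols2 = self._cols.reshape(-1, self.W.shape[0])
        self.grads[0][...] = cols2.T @ dy.reshape(-1, F)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dwin = (dy @ self.W.T).reshape(N, Lo, self._in_shape[2], self.k)
        dx = np.zeros(self._in_shape)
        idx = self.stride * np.arange(Lo)
        for j in range(self.k):
            dx[:, idx + j, :] += dwin[:, :, :, j]
        return dx


class _BatchNorm(_Layer):
    """Per-channel normalization over batch and length; moving stats at eval."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps
        self._seen = False
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            if not self._seen:  # seed moving stats from the first batch
                self.running_mean[...] = mean
                self.running_var[...] = var
                self._seen = True
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[1]
        xhat = self._xhat
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 1))
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)) / m
        ) / self._std


class _ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool1D(_Layer):
    def __init__(self, spec: PoolLayerSpec):
        self.size, self.stride = spec.pool_size, spec.stride
        self.beta, self.bias = spec.beta, spec.bias

    def forward(self, x, training):
        self._in_shape = x.shape
        win = sliding_window_view(x, self.size, axis=1)[:, :: self.stride]  # (N,Lo,C,p)
        self._argmax = win.argmax(axis=3)
        out = win.max(axis=3)
        return self.beta * out + self.bias

    def backward(self, dy):
        dy = self.beta * dy
        N, Lo, C = dy.shape
        dx = np.zeros(self._in_shape)
        pos = self.stride * np.arange(Lo)[None, :, None] + self._argmax
        n_idx = np.arange(N)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(dx, (n_idx, pos, c_idx), dy)
        return dx


class _GlobalMaxPool(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        self._argmax = x.argmax(axis=1)
        return x.max(axis=1, keepdims=True)

    def backward(self, dy):
        N, _, C = dy.shape
        dx = np.zeros(self._in_shape)
        n_idx = np.arange(N)[:, None]
        c_idx = np.arange(C)[None, :]
        np.add.at(dx, (n_idx, self._argmax, c_idx), dy[:, 0, :])
        return dx


class _Flatten(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, std, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# classifier
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    shuffle: bool = True


class CNNClassifier(BaseClassifier):
    """Trainable network built from a :class:`CNNArchitecture`.

    Training minimizes categorical cross-entropy by mini-batch Adam; batch
    normalization uses batch statistics in training mode and moving
    statistics at prediction time.
    """

    def __init__(self, arch: CNNArchitecture | None = None,
                 train_config: TrainConfig | None = None):
        self.arch = arch or default_architecture()
        self.train_config = train_config or TrainConfig()
        self.layers: list[_Layer] = []
        self.loss_history: list[float] = []
        # validate eagerly: bad architectures fail before any training
        cnn_output_shapes(self.arch)

    def _build(self, rng: np.random.Generator) -> None:
        arch = self.arch
        layers: list[_Layer] = []
        C = 1
        L = arch.input_length
        for spec in arch.features:
            if isinstance(spec, ConvLayerSpec):
                layers.append(_Conv1D(spec, C, rng))
                L, C = spec.out_length(L), spec.n_filters
                if spec.batch_norm:
                    layers.append(_BatchNorm(C))
                layers.append(_ReLU())
            elif isinstance(spec, PoolLayerSpec):
                layers.append(_MaxPool1D(spec))
                L = spec.out_length(L)
            elif isinstance(spec, GlobalMaxPoolSpec):
                layers.append(_GlobalMaxPool())
                L = 1
        layers.append(_Flatten())
        width = L * C
        for units in arch.dense_units:
            layers.append(_Dense(width, units, rng))
            layers.append(_ReLU())
            width = units
        layers.append(_Dense(width, arch.n_classes, rng))
        self.layers = layers

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        a = X[:, :, None]  # (N, L, 1)
        for layer in self.layers:
            a = layer.forward(a, training)
        return a  # logits

    def runtime_shapes(self, n: int = 2) -> list[tuple[int, ...]]:
        """Actual per-sample tensor shapes of a forward pass (shape oracle check)."""
        if not self.layers:
            self._build(np.random.default_rng(self.train_config.seed))
        X = np.zeros((n, self.arch.input_length))
        shapes = []
        a = X[:, :, None]
        for layer in self.layers:
            a = layer.forward(a, True)
            shapes.append(a.shape[1:])
        return shapes

    def fit(self, X, y) -> "CNNClassifier":
        X, y = check_Xy(X, y)
        cfg = self.train_config
        arch = self.arch
        if X.shape[1] != arch.input_length:
            raise TrainingError(
                f"input width {X.shape[1]} does not match architecture "
                f"input length {arch.input_length}"
            )
        present = np.unique(y)
        missing = sorted(set(range(arch.n_classes)) - set(present.tolist()))
        if missing:
            raise TrainingError(f"training set has no samples of class(es) {missing}")
        T = one_hot(y, arch.n_classes)
        rng = np.random.default_rng(cfg.seed)
        self._build(rng)
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        opt = _Adam(params, lr=cfg.learning_rate)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        self.loss_history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n) if cfg.shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                logits = self._forward(X[idx], training=True)
                probs = _softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(idx.size), y[idx]] + eps))
                epoch_loss += loss * idx.size
                dlogits = (probs - T[idx]) / idx.size
                d = dlogits
                for layer in reversed(self.layers):
                    d = layer.backward(d)
                opt.step(grads)
            self.loss_history.append(epoch_loss / n)
            if not np.isfinite(self.loss_history[-1]):
                raise TrainingError("CNN training diverged: loss is non-finite")
        return self

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.layers:
            raise TrainingError("model is not fitted")
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self._forward(X[start : start + batch_size], training=False)
            out.append(_softmax(logits))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
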