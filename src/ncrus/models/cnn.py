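"""A compact NumPy engine for the 1D convolutional RWC regression network.

The network consumes a standardized [601 x 2] spectrum (magnitude and phase
channels) and regresses a single RWC value. Architecture, in order: three
convolution blocks (17, 55 and 70 kernels of sizes 11, 7 and 11, each
followed by batch normalization and ReLU, the last two blocks followed by
max-pooling with window 2), then three fully connected layers of 25, 25 and 1
units with 30% dropout after the first two, and a mean-squared-error
regression output — 18 layers counting the input and regression layers.

Training uses stochastic gradient descent with momentum (0.8247), minibatches
of 32, an initial learning rate of 0.0875 with three drops of factor 10 at
the quarter points of the epoch budget, and an L2 penalty of 1.25e-7.
Convolutions are same-padded with stride 1; they are evaluated as an im2col
matrix product so the heavy lifting stays inside BLAS. Weights use a uniform
fan-in initialization driven by the run seed; all arithmetic is float32 by
default (float64 is available for gradient checking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError, ModelStateError, TrainingFailureError

__all__ = ["CnnConfig", "CnnRegressor", "build_cnn", "train_cnn", "predict_cnn"]


@dataclass(frozen=True)
class CnnConfig:
    """Hyperparameters of the 1D CNN regressor (defaults are the working set)."""

    conv_kernel_counts: tuple[int, int, int] = (17, 55, 70)
    conv_kernel_sizes: tuple[int, int, int] = (11, 7, 11)
    fc_sizes: tuple[int, int, int] = (25, 25, 1)
    dropout_prob: float = 0.30
    pool_window: int = 2
    epochs: int = 350
    minibatch: int = 32
    initial_lr: float = 0.0875
    lr_drop_count: int = 3
    lr_drop_factor: float = 10.0
    l2: float = 1.25e-7
    momentum: float = 0.8247
    grad_clip_norm: float = 1.0
    seed: int = 0
    input_length: int = 601
    input_channels: int = 2

    def lr_drop_epochs(self) -> tuple[int, ...]:
        """1-based epochs at which the learning rate divides by the drop factor."""
        return tuple(
            math.ceil(self.epochs * k / (self.lr_drop_count + 1))
            for k in range(1, self.lr_drop_count + 1)
        )


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Layer:
    kind = "layer"
    detail = ""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class _Input(_Layer):
    kind = "input"

    def __init__(self, length: int, channels: int):
        self.detail = f"[{length} x {channels}]"

    def forward(self, x, training):
        return x

    def backward(self, dy):
        return dy


class _Conv1D(_Layer):
    kind = "conv"
    #: first conv layer skips input-gradient computation (nothing learns below it)
    is_first = False

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.detail = f"{out_ch} kernels of size {kernel}"
        fan_in = in_ch * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, (fan_in, out_ch)).astype(dtype)
        self.b = rng.uniform(-bound, bound, out_ch).astype(dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._pad = ((kernel - 1) // 2, kernel // 2)

    def forward(self, x, training):
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), self._pad, (0, 0)))
        cols = sliding_window_view(xp, self.kernel, axis=1)  # (N, L, C, K)
        # weight layout: row index = channel * kernel + tap, matching the
        # (N, L, C, K) window view flattened over its last two axes
        self._cols2d = np.ascontiguousarray(cols).reshape(n * length, -1)
        self._shape = (n, length)
        y = self._cols2d @ self.w
        return y.reshape(n, length, self.out_ch) + self.b

    def backward(self, dy):
        n, length = self._shape
        dy2d = dy.reshape(n * length, self.out_ch)
        self.dw[...] = self._cols2d.T @ dy2d
        self.db[...] = dy2d.sum(axis=0)
        if self.is_first:
            return None
        dcols = (dy2d @ self.w.T).reshape(n, length, self.in_ch, self.kernel)
        dxp = np.zeros((n, length + self.kernel - 1, self.in_ch), dtype=dy.dtype)
        for k in range(self.kernel):
            dxp[:, k : k + length, :] += dcols[:, :, :, k]
        left = self._pad[0]
        return dxp[:, left : left + length, :]

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _BatchNorm(_Layer):
    kind = "batchnorm"

    def __init__(self, channels: int, dtype, eps: float = 1e-5, bn_momentum: float = 0.9):
        self.detail = f"{channels} channels"
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.bn_momentum = bn_momentum

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            m = x.size // x.shape[-1]
            flat = x.reshape(m, x.shape[-1])
            mean = flat.mean(axis=0)
            # single fused pass for the second moment
            var = np.einsum("mc,mc->c", flat, flat) / m - mean**2
            var = np.maximum(var, 0.0)
            self.running_mean = (
                self.bn_momentum * self.running_mean + (1 - self.bn_momentum) * mean
            )
            self.running_var = (
                self.bn_momentum * self.running_var + (1 - self.bn_momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        c = dy.shape[-1]
        dy2 = dy.reshape(-1, c)
        xhat2 = self._xhat.reshape(-1, c)
        self.dgamma[...] = np.einsum("mc,mc->c", dy2, xhat2)
        self.dbeta[...] = dy2.sum(axis=0)
        m = self._m
        dx = dy2 * (self.gamma * self._inv_std)
        dx -= (self.gamma * self._inv_std / m) * self.dbeta
        dx -= xhat2 * ((self.gamma * self._inv_std / m) * self.dgamma)
        return dx.reshape(dy.shape)

    def params_and_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU(_Layer):
    kind = "relu"

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool(_Layer):
    kind = "maxpool"

    def __init__(self, window: int):
        self.window = window
        self.detail = f"window {window}"

    def forward(self, x, training):
        n, length, c = x.shape
        self._in_length = length
        lt = (length // self.window) * self.window
        if self.window == 2:
            a, b = x[:, 0:lt:2, :], x[:, 1:lt:2, :]
            self._first_wins = a >= b  # ties go to the earlier position
            return np.where(self._first_wins, a, b)
        xr = x[:, :lt].reshape(n, lt // self.window, self.window, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        n, lp, c = dy.shape
        dx = np.zeros((n, self._in_length, c), dtype=dy.dtype)
        if self.window == 2:
            first = self._first_wins
            dx[:, 0 : 2 * lp : 2, :] = np.where(first, dy, 0)
            dx[:, 1 : 2 * lp : 2, :] = np.where(first, 0, dy)
            return dx
        dxr = np.zeros((n, lp, self.window, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx[:, : lp * self.window] = dxr.reshape(n, lp * self.window, c)
        return dx


class _Dense(_Layer):
    kind = "fc"

    def __init__(self, in_dim: int, out_dim: int, rng, dtype):
        self.detail = f"{out_dim} units"
        bound = 1.0 / math.sqrt(in_dim)
        self.w = rng.uniform(-bound, bound, (in_dim, out_dim)).astype(dtype)
        self.b = rng.uniform(-bound, bound, out_dim).astype(dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._in_shape = x.shape
        x2d = x.reshape(x.shape[0], -1)
        self._x2d = x2d
        return x2d @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x2d.T @ dy
        self.db[...] = dy.sum(axis=0)
        return (dy @ self.w.T).reshape(self._in_shape)

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _Dropout(_Layer):
    kind = "dropout"

    def __init__(self, prob: float, rng):
        self.prob = prob
        self.rng = rng
        self.detail = f"p={prob}"

    def forward(self, x, training):
        if not training or self.prob == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.prob) / (1.0 - self.prob)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _RegressionOutput(_Layer):
    kind = "regression"
    detail = "mean-squared-error"

    def forward(self, x, training):
        return x

    def backward(self, dy):
        return dy


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class CnnRegressor:
    """The 1D CNN RWC regressor, trainable with SGDM.

    Build via :func:`build_cnn`; ``fit`` standardizes inputs per channel with
    training-set statistics, trains with the config's schedule and returns the
    per-epoch loss trace; ``predict`` runs in inference mode (batch-norm
    running statistics, dropout off).
    """

    def __init__(self, cfg: CnnConfig, dtype=np.float32):
        if len(cfg.conv_kernel_counts) != len(cfg.conv_kernel_sizes):
            raise ConfigurationError("kernel count / size tuples must match in length")
        self.cfg = cfg
        self.dtype = dtype
        self.rng = np.random.default_rng(cfg.seed)
        self.layers: list[_Layer] = []
        self._build()
        self.trained = False
        self.input_mean = np.zeros(cfg.input_channels, dtype=dtype)
        self.input_std = np.ones(cfg.input_channels, dtype=dtype)

    def _build(self) -> None:
        cfg = self.cfg
        length, channels = cfg.input_length, cfg.input_channels
        self.layers.append(_Input(length, channels))
        n_conv = len(cfg.conv_kernel_counts)
        for i, (count, size) in enumerate(zip(cfg.conv_kernel_counts, cfg.conv_kernel_sizes)):
            conv = _Conv1D(channels, count, size, self.rng, self.dtype)
            conv.is_first = i == 0
            self.layers.append(conv)
            self.layers.append(_BatchNorm(count, self.dtype))
            self.layers.append(_ReLU())
            channels = count
            if i >= n_conv - 2:  # pool after the last two conv blocks
                self.layers.append(_MaxPool(cfg.pool_window))
                length = length // cfg.pool_window
        flat = length * channels
        for j, units in enumerate(cfg.fc_sizes):
            self.layers.append(_Dense(flat, units, self.rng, self.dtype))
            flat = units
            if j < len(cfg.fc_sizes) - 1:
                self.layers.append(_Dropout(cfg.dropout_prob, self.rng))
        self.layers.append(_RegressionOutput())

    # -- introspection ------------------------------------------------------

    def architecture(self) -> list[tuple[str, str]]:
        """The layer enumeration as (kind, detail) pairs, input through output."""
        return [(layer.kind, layer.detail) for layer in self.layers]

    def parameter_count(self) -> int:
        """Total learnable parameters (batch-norm running stats excluded)."""
        return sum(p.size for layer in self.layers for p, _ in layer.params_and_grads())

    # -- computation --------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.input_length or x.shape[2] != cfg.input_channels:
            raise ConfigurationError(
                f"expected input of shape (n, {cfg.input_length}, {cfg.input_channels}), "
                f"got {x.shape}"
            )
        return x

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def _backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:  # first conv: no layer below needs an input gradient
                break

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Raw forward pass on already-standardized input; returns (n,) outputs."""
        return self._forward(self._check_input(x), training)[:, 0]

    def fit(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        """Train with SGDM on (n, length, channels) inputs; returns the loss trace."""
        cfg = self.cfg
        x = self._check_input(x)
        y = np.asarray(y, dtype=self.dtype)
        if x.shape[0] != y.shape[0] or x.shape[0] == 0:
            raise ConfigurationError("inputs and targets must align and be nonempty")
        self.input_mean = x.mean(axis=(0, 1))
        self.input_std = x.std(axis=(0, 1))
        self.input_std[self.input_std == 0] = 1.0
        x = (x - self.input_mean) / self.input_std

        velocities = [
            [np.zeros_like(p) for p, _ in layer.params_and_grads()] for layer in self.layers
        ]
        drop_epochs = cfg.lr_drop_epochs()
        n = x.shape[0]
        trace: list[float] = []
        for epoch in range(1, cfg.epochs + 1):
            lr = cfg.initial_lr / cfg.lr_drop_factor ** sum(epoch >= d for d in drop_epochs)
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.minibatch):
                idx = order[start : start + cfg.minibatch]
                xb, yb = x[idx], y[idx]
                pred = self._forward(xb, training=True)[:, 0]
                err = pred - yb
                loss = float(np.mean(err**2))
                epoch_loss += loss * idx.size
                self._backward((2.0 * err / idx.size)[:, None].astype(self.dtype))
                # global gradient-norm clipping: the flattened conv output is
                # ~10^4-dimensional, so raw MSE gradients exceed the stable
                # step size at the configured learning rate
                if cfg.grad_clip_norm > 0:
                    total = math.sqrt(
                        sum(
                            float(np.sum(g.astype(np.float64) ** 2))
                            for layer in self.layers
                            for _, g in layer.params_and_grads()
                        )
                    )
                    if total > cfg.grad_clip_norm:
                        scale = self.dtype(cfg.grad_clip_norm / total)
                        for layer in self.layers:
                            for _, g in layer.params_and_grads():
                                g *= scale
                for layer, vels in zip(self.layers, velocities):
                    for (p, g), v in zip(layer.params_and_grads(), vels):
                        v *= cfg.momentum
                        v -= lr * (g + cfg.l2 * p)
                        p += v
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise TrainingFailureError(
                    f"non-finite training loss at epoch {epoch}; config: {cfg}"
                )
            trace.append(epoch_loss)
        self.trained = True
        return trace

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """RWC predictions for (n, length, channels) inputs, unclamped."""
        if not self.trained:
            raise ModelStateError("model has not been trained")
        x = self._check_input(x)
        x = (x - self.input_mean) / self.input_std
        out = [
            self._forward(x[i : i + batch_size], training=False)[:, 0]
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out).astype(float)


def build_cnn(cfg: CnnConfig | None = None, dtype=np.float32) -> CnnRegressor:
    """Construct an untrained CNN regressor from a config."""
    return CnnRegressor(cfg or CnnConfig(), dtype=dtype)


def train_cnn(model: CnnRegressor, x: np.ndarray, y: np.ndarray) -> list[float]:
    """Train ``model`` in place; returns the per-epoch training-loss trace."""
    return model.fit(x, y)


def predict_cnn(model: CnnRegressor, x: np.ndarray) -> np.ndarray:
    return model.predict(x)
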