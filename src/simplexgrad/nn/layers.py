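"""Layers with explicit forward/backward passes.

Array convention: convolutional tensors are (batch, length, channels).
Each layer stores its parameters in ``params`` and, after ``backward``,
their gradients in ``grads``; ``regularized`` names the parameters subject
to L2 weight decay (batch-norm parameters are exempt).
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict
    regularized: tuple = ()

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    @property
    def state(self) -> dict:
        """Non-trainable buffers to include in checkpoints."""
        return {}


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding and stride 1 (im2col matmul)."""

    regularized = ("W", "b")

    def __init__(self, in_channels: int, filters: int, kernel: int, rng, gain: float = 1.0, dtype=np.float32):
        super().__init__()
        self.k = kernel
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kernel * in_channels
        std = gain * np.sqrt(2.0 / fan_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(fan_in, filters)).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self._pad_left = (kernel - 1) // 2
        self._pad_right = kernel - 1 - self._pad_left

    def forward(self, x, training, rng):
        n, length, c = x.shape
        k = self.k
        xp = np.zeros((n, length + k - 1, c), dtype=x.dtype)
        xp[:, self._pad_left : self._pad_left + length] = x
        cols = np.empty((n, length, k, c), dtype=x.dtype)
        for j in range(k):
            cols[:, :, j, :] = xp[:, j : j + length, :]
        self._cols = cols.reshape(n * length, k * c)
        self._shape = (n, length, c)
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, length, self.filters)

    def backward(self, dout):
        n, length, c = self._shape
        k = self.k
        dout_rs = dout.reshape(n * length, self.filters)
        self.grads = {"W": self._cols.T @ dout_rs, "b": dout_rs.sum(axis=0)}
        dcols = (dout_rs @ self.params["W"].T).reshape(n, length, k, c)
        dxp = np.zeros((n, length + k - 1, c), dtype=dout.dtype)
        for j in range(k):
            dxp[:, j : j + length, :] += dcols[:, :, j, :]
        return dxp[:, self._pad_left : self._pad_left + length, :]


class Dense(Layer):
    regularized = ("W", "b")

    def __init__(self, in_features: int, out_features: int, rng, gain: float = 1.0, dtype=np.float32):
        super().__init__()
        std = gain * np.sqrt(2.0 / in_features)
        self.params = {
            "W": rng.normal(0.0, std, size=(in_features, out_features)).astype(dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    Training uses batch statistics and updates exponential running averages;
    evaluation (and hence attribution) uses the running statistics, making
    the layer an affine map so input gradients are well defined.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3, dtype=np.float32):
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    @property
    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.grads = {
            "gamma": (dout * self._xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        dxhat = dout * self.params["gamma"]
        if not self._training:
            return dxhat / self._std
        m_mean = dxhat.mean(axis=axes)
        mx_mean = (dxhat * self._xhat).mean(axis=axes)
        return (dxhat - m_mean - self._xhat * mx_mean) / self._std


class MaxPool1D(Layer):
    """Non-overlapping max pooling (size == stride); a trailing remainder is dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, training, rng):
        n, length, c = x.shape
        lp = length // self.size
        self._in_shape = x.shape
        xr = x[:, : lp * self.size, :].reshape(n, lp, self.size, c)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        n, length, c = self._in_shape
        lp = length // self.size
        dxr = np.zeros((n, lp, self.size, c), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : lp * self.size, :] = dxr.reshape(n, lp * self.size, c)
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ExpActivation(Layer):
    """Exponential activation with an input clamp to keep early training stable."""

    def __init__(self, cap: float = 10.0):
        super().__init__()
        self.cap = cap

    def forward(self, x, training, rng):
        self._mask = x < self.cap
        self._y = np.exp(np.minimum(x, self.cap))
        return self._y

    def backward(self, dout):
        return dout * self._y * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when training with an rng supplied."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if training and rng is not None and self.rate > 0:
            u = rng.random(x.shape, dtype=np.float32)
            self._mask = ((u >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)
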