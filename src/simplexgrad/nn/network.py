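"""Sequential network container and the binary cross-entropy loss."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


class Network:
    """A sequential stack of layers with reverse-mode differentiation to the input."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate; fills each layer's ``grads`` and returns d(out)/d(input)."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (i, name), value

    def gradients(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name), layer.grads[name]

    def add_l2_gradient(self, strength: float) -> None:
        """Add d/dW of strength * sum(W^2) for regularized parameters."""
        if strength <= 0:
            return
        for layer in self.layers:
            for name in layer.regularized:
                layer.grads[name] = layer.grads[name] + 2.0 * strength * layer.params[name]

    def l2_loss(self, strength: float) -> float:
        if strength <= 0:
            return 0.0
        total = 0.0
        for layer in self.layers:
            for name in layer.regularized:
                total += float(np.sum(layer.params[name].astype(np.float64) ** 2))
        return strength * total

    def get_weights(self) -> list[dict]:
        snap = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            entry["__state__"] = copy.deepcopy({k: v.copy() for k, v in layer.state.items()})
            snap.append(entry)
        return snap

    def set_weights(self, snapshot: list[dict]) -> None:
        for layer, entry in zip(self.layers, snapshot):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            for k, v in entry.get("__state__", {}).items():
                setattr(layer, k, v.copy())

    def summary(self, input_shape: tuple) -> list[tuple[str, tuple, int]]:
        """Run a dummy forward and report (layer, output shape, parameter count)."""
        x = np.zeros((1,) + tuple(input_shape), dtype=np.float32)
        rows = []
        for layer in self.layers:
            x = layer.forward(x, False, None)
            rows.append((type(layer).__name__, x.shape[1:], layer.n_params))
        return rows

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = logits.reshape(-1).astype(np.float64)
    y = y.reshape(-1).astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / z.size).reshape(logits.shape)
    return loss, grad
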