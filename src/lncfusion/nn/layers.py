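"""Minimal numpy neural-network layers with explicit backpropagation.

Implements exactly what the classifier needs: dense stacks, a 1-D
convolutional block (convolution -> batch normalization -> ReLU -> max
pooling), dropout, and sigmoid/binary-cross-entropy heads.  All layers are
deterministic given a seeded ``numpy.random.Generator``.

Conventions: dense inputs are ``(n, features)``; convolutional inputs are
``(n, channels, length)``.  ``forward`` caches what ``backward`` needs;
``backward`` consumes the gradient w.r.t. the output and returns the
gradient w.r.t. the input, accumulating parameter gradients in ``grads``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter-free identity."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He initialization (ReLU stacks)
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Conv1D(Layer):
    """Valid cross-correlation, stride 1: (n, c_in, L) -> (n, c_out, L-k+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.kernel = kernel
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"input length {x.shape[2]} shorter than kernel {self.kernel}")
        self._x = x
        # windows: (n, c_in, L_out, k)
        win = sliding_window_view(x, self.kernel, axis=2)
        self._win = win
        return np.einsum("nclk,ock->nol", win, self.params["W"],
                         optimize=True) + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("nclk,nol->ock", self._win, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        W = self.params["W"]
        L_out = dy.shape[2]
        for j in range(self.kernel):
            dx[:, :, j:j + L_out] += np.einsum("nol,oc->ncl", dy, W[:, :, j],
                                               optimize=True)
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and length axis for 3-D input).

    A frozen (``trainable = False``) layer runs in inference mode even
    during training: running statistics are used and left untouched.
    """

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _axes_shape(self, x: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 3:
            return (0, 2), (1, -1, 1)
        raise ValueError(f"BatchNorm expects 2-D or 3-D input, got {x.ndim}-D")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes, shape = self._axes_shape(x)
        gamma = self.params["gamma"].reshape(shape)
        beta = self.params["beta"].reshape(shape)
        if training and self.trainable:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            self._axes = axes
            self._m = x.size // mean.size
            self._xhat = (x - mean.reshape(shape)) / np.sqrt(
                var.reshape(shape) + self.eps)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._train_pass = True
            return gamma * self._xhat + beta
        self._train_pass = False
        xhat = (x - self.running_mean.reshape(shape)) / np.sqrt(
            self.running_var.reshape(shape) + self.eps)
        self._xhat = xhat
        return gamma * xhat + beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, shape = self._axes_shape(dy)
        gamma = self.params["gamma"].reshape(shape)
        if not self._train_pass:
            # inference-mode pass: statistics are constants
            self.grads["gamma"] = (dy * self._xhat).sum(
                axis=self._axes_shape(dy)[0])
            self.grads["beta"] = dy.sum(axis=self._axes_shape(dy)[0])
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            return dy * gamma * inv.reshape(shape)
        axes = self._axes
        m = self._m
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * gamma
        inv_std = self._inv_std.reshape(shape)
        return (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        )


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder
    positions are dropped)."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, L = x.shape
        L_out = L // self.pool
        if L_out == 0:
            raise ValueError(f"input length {L} shorter than pool {self.pool}")
        self._in_shape = x.shape
        xr = x[:, :, :L_out * self.pool].reshape(n, c, L_out, self.pool)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L_out = dy.shape
        dxr = np.zeros((n, c, L_out, self.pool))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, :L_out * self.pool] = dxr.reshape(n, c, L_out * self.pool)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def set_trainable(self, flag: bool) -> None:
        for layer in self.iter_layers():
            layer.trainable = flag

    def iter_layers(self) -> Iterator[Layer]:
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer

    def named_params(self, prefix: str = "") -> Iterator[tuple[str, Layer, str]]:
        """Yield (qualified name, owning layer, param key) triples."""
        for i, layer in enumerate(self.layers):
            name = f"{prefix}{i}"
            if isinstance(layer, Sequential):
                yield from layer.named_params(prefix=f"{name}.")
            else:
                for key in layer.params:
                    yield f"{name}.{key}", layer, key

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus batch-norm running statistics, by name."""
        out = {name: layer.params[key] for name, layer, key in self.named_params()}
        for i, layer in enumerate(self.iter_layers()):
            if isinstance(layer, BatchNorm):
                out[f"bn{i}.running_mean"] = layer.running_mean
                out[f"bn{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params[key] = np.array(state[name])
        for i, layer in enumerate(self.iter_layers()):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(state[f"bn{i}.running_mean"])
                layer.running_var = np.array(state[f"bn{i}.running_var"])


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    # log(1+exp(-|z|)) form is overflow-safe
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(-1, 1)
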