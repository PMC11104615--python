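"""Minimal neural-network layers with explicit forward/backward passes.

All layers operate on NumPy arrays. Shapes follow the 1-D convolutional
convention ``(batch, channels, length)`` for convolutional layers and
``(batch, features)`` for fully connected layers. Each layer caches what it
needs during ``forward`` and returns the input gradient from ``backward``,
accumulating parameter gradients in ``self.grads``.

Float32 is used throughout: trace intensities are O(1) and the optimiser is
first-order, so single precision is ample and roughly halves training time.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameter-free layers only need forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": _uniform_init(rng, (n_out, n_in), n_in),
            "b": _uniform_init(rng, (n_out,), n_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Tanh(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y * self._y)


def conv_output_length(length: int, kernel: int, stride: int, padding: int) -> int:
    """Temporal length after a strided 1-D convolution."""
    return (length + 2 * padding - kernel) // stride + 1


class Conv1d(Layer):
    """Strided 1-D convolution via an im2col matmul."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 2,
        padding: int = 1,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = c_in * kernel
        self.params = {
            "W": _uniform_init(rng, (c_out, c_in, kernel), fan_in),
            "b": _uniform_init(rng, (c_out,), fan_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, s, p = self.kernel, self.stride, self.padding
        L_out = conv_output_length(L, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.empty((B, C, L_out, k), dtype=x.dtype)
        for j in range(k):
            cols[:, :, :, j] = xp[:, :, j : j + s * (L_out - 1) + 1 : s]
        self._cols = cols
        self._in_shape = (B, C, L)
        W = self.params["W"].reshape(self.c_out, C * k)
        y = cols.transpose(0, 2, 1, 3).reshape(B, L_out, C * k) @ W.T
        return y.transpose(0, 2, 1) + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        k, s, p = self.kernel, self.stride, self.padding
        L_out = dy.shape[2]
        dyt = dy.transpose(0, 2, 1).reshape(B * L_out, self.c_out)
        cols_flat = self._cols.transpose(0, 2, 1, 3).reshape(B * L_out, C * k)
        self.grads["W"] += (dyt.T @ cols_flat).reshape(self.c_out, C, k)
        self.grads["b"] += dy.sum(axis=(0, 2))
        dcols = (dyt @ self.params["W"].reshape(self.c_out, C * k)).reshape(
            B, L_out, C, k
        ).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + 2 * p), dtype=dy.dtype)
        for j in range(k):
            dxp[:, :, j : j + s * (L_out - 1) + 1 : s] += dcols[:, :, :, j]
        return dxp[:, :, p : p + L] if p else dxp


def conv_transpose_output_length(
    length: int, kernel: int, stride: int, padding: int, output_padding: int
) -> int:
    return (length - 1) * stride - 2 * padding + kernel + output_padding


class ConvTranspose1d(Layer):
    """Transposed 1-D convolution (the adjoint of :class:`Conv1d`)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 2,
        padding: int = 1,
        output_padding: int = 0,
    ) -> None:
        super().__init__()
        if not 0 <= output_padding < stride:
            raise ValueError("output_padding must lie in [0, stride)")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        fan_in = c_in * kernel
        self.params = {
            "W": _uniform_init(rng, (c_in, c_out, kernel), fan_in),
            "b": _uniform_init(rng, (c_out,), fan_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        self._x = x
        L_full = (L - 1) * s + k
        L_out = conv_transpose_output_length(L, k, s, p, op)
        y_full = np.zeros((B, self.c_out, L_full), dtype=x.dtype)
        xt = x.transpose(0, 2, 1)  # (B, L, C)
        for j in range(k):
            y_full[:, :, j : j + s * (L - 1) + 1 : s] += (
                xt @ self.params["W"][:, :, j]
            ).transpose(0, 2, 1)
        y = y_full[:, :, p : p + L_out]
        return y + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, L = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        L_full = (L - 1) * s + k
        dy_full = np.zeros((B, self.c_out, L_full), dtype=dy.dtype)
        dy_full[:, :, p : p + dy.shape[2]] = dy
        dx = np.zeros_like(x)
        xt = x.transpose(0, 2, 1)
        for j in range(k):
            sl = dy_full[:, :, j : j + s * (L - 1) + 1 : s]  # (B, c_out, L)
            dx += (sl.transpose(0, 2, 1) @ self.params["W"][:, :, j].T).transpose(0, 2, 1)
            self.grads["W"][:, :, j] += np.einsum("blc,bol->co", xt, sl)
        self.grads["b"] += dy.sum(axis=(0, 2))
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over the channel axis of (B, C, L) input."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None
        self._train_mode = True

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._train_mode = train
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
            self._cache = (xhat, inv_std)
            return g * xhat + b
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std)
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        g = self.params["gamma"][None, :, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        dxhat = dy * g
        if not self._train_mode:
            return dxhat * inv_std[None, :, None]
        B, _, L = dy.shape
        n = B * L
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend((layer, k) for k in layer.params)
        return out


class Adam:
    """Adam optimiser over a list of (layer, parameter-name) handles."""

    def __init__(
        self,
        handles: list[tuple[Layer, str]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.handles = handles
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in handles]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in handles]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (layer, k) in enumerate(self.handles):
            g = layer.grads[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[k].dtype
            )
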