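"""Minimal 1-D convolutional network machinery on numpy.

Implements exactly the layer set the intensity model needs — Conv1D with
same-padding (stride 1), ReLU, non-overlapping MaxPool1D, Flatten and Dense
— with hand-written backpropagation and an Adam optimizer. Inputs are
(N, channels, length) arrays; all initialization is driven by a
caller-supplied numpy Generator so builds are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Stride-1 cross-correlation with zero same-padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("same-padding Conv1D requires an odd kernel")
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel
        # He initialization: the layer is always followed by ReLU
        weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        bias = np.zeros(c_out)
        self.params = [weight, bias]
        self.grads = [np.zeros_like(weight), np.zeros_like(bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        weight, bias = self.params
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # (N, C_in, L, k) windows
        self._cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        out = np.einsum("nclk,ock->nol", self._cols, weight, optimize=True)
        return out + bias[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        weight, _ = self.params
        self.grads[0][...] = np.einsum("nclk,nol->ock", self._cols, grad, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        n, c_in, length = self._cols.shape[0], self._cols.shape[1], grad.shape[2]
        dxp = np.zeros((n, c_in, length + 2 * self.pad))
        for t in range(self.kernel):
            dxp[:, :, t : t + length] += np.einsum(
                "ock,nol->ncl", weight[:, :, t : t + 1], grad, optimize=True
            )
        return dxp[:, :, self.pad : self.pad + length]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing odd element is dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        out_len = length // self.size
        if out_len == 0:
            raise ValueError(f"pooled length 0 from input length {length}")
        self._in_shape = x.shape
        windows = x[:, :, : out_len * self.size].reshape(n, c, out_len, self.size)
        self._argmax = windows.argmax(axis=3)
        return windows.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, out_len = grad.shape
        dwin = np.zeros((n, c, out_len, self.size))
        ni, ci, li = np.indices((n, c, out_len))
        dwin[ni, ci, li, self._argmax] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :, : out_len * self.size] = dwin.reshape(n, c, out_len * self.size)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu_gain: bool = True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_gain else 1.0) / d_in)
        weight = rng.normal(0.0, scale, size=(d_in, d_out))
        bias = np.zeros(d_out)
        self.params = [weight, bias]
        self.grads = [np.zeros_like(weight), np.zeros_like(bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        weight, bias = self.params
        return x @ weight + bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        weight, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ weight.T


class Network:
    """A plain sequential container."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for param, saved in zip(self.parameters(), state, strict=True):
            param[...] = saved


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for param, grad, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad * grad
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries, with its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad
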