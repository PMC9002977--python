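"""Minimal 1D convolutional network, implemented on NumPy.

The feature extractor used throughout the package is small and fixed in
shape — four convolutional layers of 64 length-3 filters, batch
normalisation on every conv layer, ReLU activations, and average pooling
after the first three conv layers — so a compact, dependency-free
implementation with explicit backpropagation is used. Layers follow the
usual interface: ``forward(x, train)`` caches what ``backward(dy)`` needs;
parameters and gradients are exposed as flat lists for the SGD loop.

Input tensors are ``(N, C, L)`` float32: batch, channels, time.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "AvgPool1d",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "cross_entropy_grad",
]


class Layer:
    """Base class; stateless layers override only forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_len(self, L: int) -> int:
        return L


class Conv1d(Layer):
    """Valid (no padding), stride-1 temporal convolution via im2col."""

    def __init__(self, in_channels: int, filters: int, kernel_len: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.C, self.F, self.K = in_channels, filters, kernel_len
        fan_in = in_channels * kernel_len
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, fan_in))
        self.params = [w.astype(np.float32), np.zeros(filters, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def out_len(self, L: int) -> int:
        return L - self.K + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        Lp = L - self.K + 1
        if Lp < 1:
            raise ValueError(f"input length {L} too short for kernel {self.K}")
        cols = np.lib.stride_tricks.sliding_window_view(x, self.K, axis=2)
        # (N, C, L', K) -> (N, L', C*K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(N, Lp, C * self.K)
        self._cols = cols
        w, b = self.params
        y = cols @ w.T + b
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        N, F, Lp = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (N, L', F)
        self.grads[0][...] = np.einsum("nlf,nlc->fc", dyt, self._cols)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dcols = (dyt.reshape(-1, F) @ w).reshape(N, Lp, self.C, self.K)
        dx = np.zeros((N, self.C, Lp + self.K - 1), dtype=dy.dtype)
        for k in range(self.K):
            dx[:, :, k:k + Lp] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over batch and time."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = [np.ones(channels, dtype=np.float32),
                       np.zeros(channels, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivar[None, :, None]
        if train:
            self._cache = (xhat, ivar)
        return gamma[None, :, None] * xhat + beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        xhat, ivar = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dxhat = dy * gamma[None, :, None]
        # standard batch-norm backward, vectorised per channel
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m) * ivar[None, :, None]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool1d(Layer):
    """Average pooling, kernel = stride; an odd trailing sample is dropped."""

    def __init__(self, pool_len: int = 2) -> None:
        super().__init__()
        self.k = pool_len

    def out_len(self, L: int) -> int:
        return L // self.k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        Lo = L // self.k
        self._in_len = L
        return x[:, :, : Lo * self.k].reshape(N, C, Lo, self.k).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, Lo = dy.shape
        dx = np.zeros((N, C, self._in_len), dtype=dy.dtype)
        dx[:, :, : Lo * self.k] = np.repeat(dy / self.k, self.k, axis=2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.params = [w.astype(np.float32), np.zeros(out_dim, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w.T + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w


class Sequential:
    """Ordered layer stack with flat parameter access and state snapshots."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers for p, g in zip(layer.params, layer.grads)]

    def sgd_step(self, lr: float) -> None:
        for p, g in self.parameters():
            p -= lr * g

    def get_state(self) -> list[np.ndarray]:
        state = []
        for layer in self.layers:
            state.extend(p.copy() for p in layer.params)
            if isinstance(layer, BatchNorm1d):
                state.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = state[i]
                i += 1
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[i]
                layer.running_var[...] = state[i + 1]
                i += 2


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n
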