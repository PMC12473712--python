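"""Minimal 1-D convolutional network engine on numpy.

Exactly the pieces the identification architectures need: 1-D convolution
(same padding), ReLU, max pooling, global-average and additive-attention
temporal pooling, dense layers, softmax cross-entropy, and Adam — each with a
hand-derived backward pass.  Arrays are laid out ``(batch, length, channels)``.

The engine is deliberately small and fully deterministic: all initialisation
comes from a caller-supplied :class:`numpy.random.Generator`, and identical
seeds reproduce training bit-for-bit on a fixed numpy build.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "GlobalAvgPool",
    "AttentionPool",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding, stride 1.

    Weights ``(kernel, c_in, c_out)``, He-normal initialised.  Forward uses an
    im2col matmul; backward scatters column gradients back over the kernel
    offsets (kernel sizes here are <= 7, so the small python loop is cheap).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * c_in))
        w = rng.standard_normal((kernel, c_in, c_out)) * scale
        b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        pad_l = k // 2
        xp = np.pad(x, ((0, 0), (pad_l, k - 1 - pad_l), (0, 0)))
        # (B, L, c_in, k) -> (B, L, k, c_in)
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        self._cols, self._in_shape = cols, x.shape
        w, b = self.params
        B, L = x.shape[:2]
        y = cols.reshape(B * L, -1) @ w.reshape(-1, w.shape[-1]) + b
        return y.reshape(B, L, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        k = self.kernel
        B, L, c_in = self._in_shape
        dy_flat = dy.reshape(B * L, -1)
        self.grads[0][...] = (
            self._cols.reshape(B * L, -1).T @ dy_flat
        ).reshape(w.shape)
        self.grads[1][...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ w.reshape(-1, w.shape[-1]).T).reshape(B, L, k, c_in)
        pad_l = k // 2
        dxp = np.zeros((B, L + k - 1, c_in))
        for j in range(k):
            dxp[:, j : j + L] += dcols[:, :, j]
        return dxp[:, pad_l : pad_l + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Temporal max pooling with window/stride 2 (odd tail sample dropped)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        self._in_len = L
        half = L // 2
        xr = x[:, : half * 2].reshape(B, half, 2, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, half, C = dy.shape
        dxr = np.zeros((B, half, 2, C))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_len, C))
        dx[:, : half * 2] = dxr.reshape(B, half * 2, C)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._len, axis=1) / self._len


class AttentionPool(Layer):
    """Additive temporal attention pooling.

    A single-unit projection scores each time step, a softmax over time turns
    the scores into weights, and the output is the weighted sum of the time
    steps.  Identical time steps therefore get exactly uniform weights.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal(channels) / np.sqrt(channels)
        b = np.zeros(1)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        scores = x @ w + b[0]  # (B, L)
        alpha = softmax(scores)
        self._x, self._alpha = x, alpha
        return (alpha[:, :, None] * x).sum(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        x, alpha = self._x, self._alpha
        dalpha = (x * dy[:, None, :]).sum(axis=-1)  # (B, L)
        dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        self.grads[0][...] = (x * dscores[:, :, None]).sum(axis=(0, 1))
        self.grads[1][...] = dscores.sum()
        return alpha[:, :, None] * dy[:, None, :] + dscores[:, :, None] * w

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Attention weights for inspection, shape (B, L)."""
        w, b = self.params
        return softmax(x @ w + b[0])


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend(zip(layer.params, layer.grads))
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.parameters())


class Adam:
    """Adam optimiser over (param, grad) pairs, updating params in place."""

    def __init__(self, param_grads, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
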