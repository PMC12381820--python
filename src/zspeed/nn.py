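"""Minimal 1D convolutional network stack with reverse-mode gradients.

Purpose-built trainer for the short (length-101) Z-spectrum reconstruction
networks: zero-padded ``same`` convolutions, 2x max pooling, 2x nearest
upsampling, channel concatenation for skip connections, ReLU activations,
Adam, and a reduce-on-plateau learning-rate schedule.  Everything is plain
numpy, single-threaded and bit-deterministic for a fixed seed, which keeps
training histories exactly reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "MaxPool1d", "Upsample1d", "EdgePad1d", "Crop1d", "Adam"]


class Conv1d:
    """``same``-padded 1D convolution, optional ReLU.

    Weights use He-normal initialization, W ~ N(0, 2/(c_in*k)).
    """

    kind = "conv"

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = "relu"):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.activation = activation
        std = np.sqrt(2.0 / (c_in * kernel_size))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, kernel_size))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        pad = self.k // 2
        xp = np.zeros((B, C, L + 2 * pad))
        xp[:, :, pad:pad + L] = x
        # patches[b, c, t, l] = xp[b, c, l + t]
        patches = np.stack([xp[:, :, t:t + L] for t in range(self.k)], axis=2)
        y = np.einsum("oct,bctl->bol", self.W, patches, optimize=True)
        y += self.b[None, :, None]
        mask = None
        if self.activation == "relu":
            mask = y > 0
            y = y * mask
        if train:
            self._cache = (patches, mask, L)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        patches, mask, L = self._cache
        if mask is not None:
            dy = dy * mask
        self.dW = np.einsum("bol,bctl->oct", dy, patches, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        # gradient w.r.t. padded input, scattered from each tap
        dpatches = np.einsum("oct,bol->bctl", self.W, dy, optimize=True)
        B = dy.shape[0]
        pad = self.k // 2
        dxp = np.zeros((B, self.c_in, L + 2 * pad))
        for t in range(self.k):
            dxp[:, :, t:t + L] += dpatches[:, :, t, :]
        return dxp[:, :, pad:pad + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool1d:
    """Non-overlapping max pooling with window 2 (length must be even)."""

    kind = "pool"

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if L % 2:
            raise ValueError("length must be even for 2x pooling")
        xr = x.reshape(B, C, L // 2, 2)
        arg = xr.argmax(axis=3)
        if train:
            self._argmax = arg
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lh = dy.shape
        dx = np.zeros((B, C, Lh, 2))
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        return dx.reshape(B, C, Lh * 2)

    def params(self):
        return []


class Upsample1d:
    """Nearest-neighbour 2x upsampling."""

    kind = "upsample"

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        return dy.reshape(B, C, L // 2, 2).sum(axis=3)

    def params(self):
        return []


class EdgePad1d:
    """Replicate-pad the sequence end(s) so two 2x poolings divide evenly.

    Length 101 is padded to 104 (1 left, 2 right); :class:`Crop1d` undoes it
    at the output, so padding is invisible at the model interface.
    """

    kind = "pad"

    def __init__(self, left: int, right: int) -> None:
        self.left, self.right = left, right

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        parts = [np.repeat(x[:, :, :1], self.left, axis=2), x,
                 np.repeat(x[:, :, -1:], self.right, axis=2)]
        return np.concatenate(parts, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = dy.shape[2] - self.left - self.right
        dx = dy[:, :, self.left:self.left + L].copy()
        if self.left:
            dx[:, :, 0] += dy[:, :, :self.left].sum(axis=2)
        if self.right:
            dx[:, :, -1] += dy[:, :, self.left + L:].sum(axis=2)
        return dx

    def params(self):
        return []


class Crop1d:
    """Crop back to the original length after :class:`EdgePad1d`."""

    kind = "crop"

    def __init__(self, left: int, right: int) -> None:
        self.left, self.right = left, right

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._padded_len = x.shape[2]
        end = self._padded_len - self.right
        return x[:, :, self.left:end]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        dx = np.zeros((B, C, self._padded_len))
        dx[:, :, self.left:self.left + L] = dy
        return dx

    def params(self):
        return []


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, ((p, _), g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
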