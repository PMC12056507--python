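"""Differentiable layers on NumPy arrays.

Tensors are float32 in channels-last (N, H, W, C) layout, which keeps
the im2col patch matrices and the channel matmuls contiguous — the
layout choice is what makes CPU training practical.  Each layer
caches what its backward pass needs; ``backward`` consumes the
upstream gradient and returns the input gradient, accumulating
parameter gradients in ``grads`` keyed like ``params``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Conv1x1", "ReLU", "MaxPool2", "Upsample2", "Concat"]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}


class Conv3x3(Layer):
    """3×3 convolution, stride 1, 'same' zero padding, He init.

    Weight shape (9, C_in, C_out), one (C_in, C_out) block per kernel
    tap in row-major (ki, kj) order.  The forward pass is a single
    GEMM over the zero-padded frame followed by nine shifted
    slice-adds — no im2col gather — which is what keeps CPU training
    cheap.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * 9))
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": (rng.standard_normal((9, c_in, c_out)) * std).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.c_out
        W = self.params["W"]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # out(y) = Σ_k xp(y + k) · W_k: one GEMM against all 9 taps at
        # once, then accumulate the shifted views of the result
        taps = (
            xp.reshape(-1, c) @ W.transpose(1, 0, 2).reshape(c, 9 * f)
        ).reshape(n, h + 2, w + 2, 9, f)
        out = np.empty((n, h, w, f), dtype=np.float32)
        out[...] = self.params["b"]
        for k in range(9):
            ki, kj = divmod(k, 3)
            out += taps[:, ki : ki + h, kj : kj + w, k, :]
        self._cache = (xp, (n, h, w, c))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (n, h, w, c) = self._cache
        f = self.c_out
        W = self.params["W"]
        dflat = dout.reshape(-1, f)
        self.grads["b"] += dflat.sum(axis=0)
        # dxp(y + k) += dout(y) · W_k^T, again one GEMM for all taps
        Wt = np.ascontiguousarray(W.transpose(2, 0, 1)).reshape(f, 9 * c)
        G = (dflat @ Wt).reshape(n, h, w, 9, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for k in range(9):
            ki, kj = divmod(k, 3)
            dxp[:, ki : ki + h, kj : kj + w, :] += G[:, :, :, k, :]
        # dW_k = Σ_y xp(y + k) ⊗ dout(y)
        dW = self.grads["W"]
        for k in range(9):
            ki, kj = divmod(k, 3)
            sl = np.ascontiguousarray(xp[:, ki : ki + h, kj : kj + w, :]).reshape(-1, c)
            dW[k] += sl.T @ dflat
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class Conv1x1(Layer):
    """Per-pixel linear map across channels (the classifier head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": (rng.standard_normal((c_in, c_out)) * std).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        c = x.shape[-1]
        self.grads["W"] += x.reshape(-1, c).T @ dout.reshape(-1, self.c_out)
        self.grads["b"] += dout.reshape(-1, self.c_out).sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2.  Spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even dims, got {h}x{w}")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = blocks.max(axis=(2, 4))
        self._argmask = blocks == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        mask = self._argmask
        # split gradient equally among tied maxima (common after ReLU zeros)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        up = mask * (dout[:, :, None, :, None, :] / counts)
        return up.reshape(n, h, w, c).astype(np.float32)


class Upsample2(Layer):
    """Nearest-neighbor ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return dout.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)).astype(np.float32)


class Concat(Layer):
    """Channel-wise concatenation of a decoder tensor with its skip."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return dout[..., : self._split], dout[..., self._split :]
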