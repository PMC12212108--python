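"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the prototypical-part classifier needs: stride-1 'same'
convolutions via im2col, 2x2 max pooling, ReLU/sigmoid, and Adam.  Arrays
are (N, C, H, W) float64 throughout; deliberately compact rather than
general.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "MaxPool2", "ReLU", "Sigmoid", "Adam", "Sequential"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, k, k, h, w), strides=(s0, s1, s2, s3, s2, s3))
    return windows.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch columns back into an image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return out[:, :, pad:pad + h, pad:pad + w] if pad else out


class Conv2d:
    """Stride-1 convolution with 'same' padding for odd kernels."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.W = rng.standard_normal((c_out, c_in, k, k)) * scale
        self.b = np.zeros(c_out)
        self.k, self.pad = k, k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.trainable = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, hw = self._cols.shape
        h, w = x.shape[2], x.shape[3]
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.einsum("of,nfp->nop", wmat, self._cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dout.shape
        dflat = dout.reshape(n, c_out, h * w)
        if self.trainable:
            self.dW += np.einsum("nop,nfp->of", dflat, self._cols).reshape(self.W.shape)
            self.db += dflat.sum(axis=(0, 2))
        wmat = self.W.reshape(c_out, -1)
        dcols = np.einsum("of,nop->nfp", wmat, dflat)
        return _col2im(dcols, self._x_shape, self.k, self.pad)

    def params(self):
        if self.trainable:
            yield self.W, self.dW
            yield self.b, self.db


class MaxPool2:
    """2x2 max pooling, stride 2 (even input sides assumed)."""

    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self._xr_shape = xr.shape
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dout.shape
        dflat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dflat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, ho * 2, wo * 2)

    def params(self):
        return iter(())


class ReLU:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return iter(())


class Sigmoid:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)

    def params(self):
        return iter(())


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _p, g in layer.params():
                g[...] = 0.0

    def set_trainable(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                layer.trainable = flag

    def params(self):
        for layer in self.layers:
            yield from layer.params()


class Adam:
    """Adam over (param, grad) array pairs identified by position."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, param_grads) -> None:
        self.t += 1
        for i, (p, g) in enumerate(param_grads):
            if i not in self._state:
                self._state[i] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._state[i]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
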