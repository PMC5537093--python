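"""Minimal CPU neural-network engine for 2-D convolutional segmentation.

Implements exactly the layer set the encoder-decoder needs — padded 2-D
convolution (im2col + BLAS matmul), ReLU, inverted dropout, 2x2 max pooling,
2x2 nearest-neighbour upsampling — each with a hand-derived backward pass,
plus an Adam optimizer.  Data layout is (batch, channels, height, width).

Every backward pass is validated against central finite differences in the
test suite; run the engine in float64 for gradient checks, float32 for
training speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "Dropout", "MaxPool2", "Upsample2", "Adam", "sigmoid"]


def sigmoid(z):
    # numerically stable piecewise form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2D:
    """Same-padded convolution with kernel size 1 or 3, He-initialized."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng, dtype=np.float32):
        if ksize not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((c_out, c_in, ksize, ksize)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = ksize
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        k = self.k
        Wmat = self.W.reshape(self.W.shape[0], -1)  # (Cout, C*k*k)
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
            # (B, C, H, W, 3, 3) -> (B*H*W, C*9)
            cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
                B * H * W, C * 9
            )
        y = cols @ Wmat.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(B, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, x_shape = self._cache
        B, C, H, W = x_shape
        k = self.k
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(B * H * W, -1)  # (BHW, Cout)
        self.dW = (dy_mat.T @ cols).reshape(self.W.shape)
        self.db = dy_mat.sum(axis=0)
        dcols = dy_mat @ self.W.reshape(self.W.shape[0], -1)  # (BHW, C*k*k)
        if k == 1:
            dx = dcols.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        else:
            dc = dcols.reshape(B, H, W, C, 3, 3)
            dxp = np.zeros((B, C, H + 2, W + 2), dtype=dy.dtype)
            for di in range(3):
                for dj in range(3):
                    dxp[:, :, di : di + H, dj : dj + W] += dc[:, :, :, :, di, dj].transpose(
                        0, 3, 1, 2
                    )
            dx = dxp[:, :, 1 : H + 1, 1 : W + 1]
        self._cache = None
        return dx


class ReLU:
    params = ()
    grads = ()

    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity in inference mode."""

    params = ()
    grads = ()

    def __init__(self, rate: float, rng):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; gradient routed to the argmax voxel."""

    params = ()
    grads = ()

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"pooling needs even spatial dims, got {H}x{W}")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H // 2, W // 2, 4
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (B, C, H, W) = self._cache
        dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )


class Upsample2:
    """2x2 nearest-neighbour upsampling; gradient sums over each block."""

    params = ()
    grads = ()

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam with standard bias correction, one state slot per parameter."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
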