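"""Encoder-decoder voxel-classification network (U-Net family).

The model maps a 2-D slice to a per-voxel kidney probability map.  The
encoder halves resolution with 2x2 max pooling while doubling feature
count; the decoder mirrors it with 2x2 nearest-neighbour upsampling, and a
skip connection concatenates the encoder features into the decoder at every
resolution level so spatial detail survives the bottleneck.  Each level is
a block of same-padded 3x3 convolutions with ReLU followed by dropout; the
head is a 1x1 convolution with a logistic (sigmoid) activation.

3-D volumes are processed slice-by-slice and restacked; training minimizes
1 - soft Dice so the optimized quantity coincides with the monitored one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn_core import Conv2D, ReLU, Dropout, MaxPool2, Upsample2, sigmoid

__all__ = ["NetworkSpec", "UNet2D", "build_network", "soft_dice",
           "normalize_volume", "ShapeError"]


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network depth."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling levels; filters start at
    ``base_filters`` and double at each level.  Kernels are 3x3 with ReLU,
    pooling/upsampling are 2x2, and the output head is a 1x1 convolution
    with sigmoid activation.  Input height and width must be divisible by
    ``2**depth``.
    """

    depth: int = 4
    base_filters: int = 32
    convs_per_block: int = 2
    dropout_rate: float = 0.35

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**{k: d[k] for k in ("depth", "base_filters", "convs_per_block", "dropout_rate")})


DESK_SCALE_SPEC = NetworkSpec(depth=2, base_filters=8)


def soft_dice(prob, target, smooth: float = 1e-6) -> float:
    """Soft (probabilistic) Dice overlap.

    ``(2*sum(p*t) + s) / (sum(p) + sum(t) + s)``; on binary inputs with
    negligible ``s`` this reduces to the confusion-count Dice
    2TP/(2TP+FP+FN).
    """
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    inter = float((prob * target).sum())
    denom = float(prob.sum() + target.sum())
    return (2.0 * inter + smooth) / (denom + smooth)


def normalize_volume(values) -> np.ndarray:
    """Per-volume z-score normalization applied before training/inference."""
    values = np.asarray(values, dtype=np.float32)
    sd = float(values.std())
    if sd == 0:
        return values - float(values.mean())
    return (values - float(values.mean())) / sd


class _Block:
    """convs_per_block x (Conv3x3 -> ReLU), then Dropout."""

    def __init__(self, c_in, c_out, n_convs, rate, rng, dtype):
        self.layers = []
        c = c_in
        for _ in range(n_convs):
            self.layers += [Conv2D(c, c_out, 3, rng, dtype), ReLU()]
            c = c_out
        self.layers.append(Dropout(rate, rng))

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        return iter(self.layers)


class UNet2D:
    """The encoder-decoder model with explicit forward/backward passes.

    Weight initialization and dropout draws are fully determined by
    ``seed``: two models built from the same ``(spec, seed)`` are
    identical.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(self.seed)
        d, f, c, r = spec.depth, spec.base_filters, spec.convs_per_block, spec.dropout_rate

        self.enc_blocks, self.pools = [], []
        c_in = 1
        for i in range(d):
            self.enc_blocks.append(_Block(c_in, f * 2**i, c, r, rng, dtype))
            self.pools.append(MaxPool2())
            c_in = f * 2**i
        self.bottleneck = _Block(c_in, f * 2**d, c, r, rng, dtype)

        self.ups, self.dec_blocks = [], []
        c_prev = f * 2**d
        for i in reversed(range(d)):
            self.ups.append(Upsample2())
            self.dec_blocks.append(_Block(c_prev + f * 2**i, f * 2**i, c, r, rng, dtype))
            c_prev = f * 2**i
        self.head = Conv2D(c_prev, 1, 1, rng, dtype)
        self._skip_channels = [f * 2**i for i in range(d)]

    # -- parameter plumbing -------------------------------------------------
    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk.iter_layers()
        yield from self.bottleneck.iter_layers()
        for blk in self.dec_blocks:
            yield from blk.iter_layers()
        yield self.head

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.grads)
        return out

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w.astype(p.dtype)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------
    def _check_dims(self, H, W):
        div = 2**self.spec.depth
        if H % div or W % div:
            raise ShapeError(
                f"in-plane dimensions {H}x{W} must be divisible by 2^depth = {div}"
            )

    def forward_logits(self, x, train=False):
        """x: (B, 1, H, W) -> logits (B, 1, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        B, C, H, W = x.shape
        self._check_dims(H, W)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for j, i in enumerate(reversed(range(self.spec.depth))):
            h = self.ups[j].forward(h, train)
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.dec_blocks[j].forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits):
        d = self.spec.depth
        dh = self.head.backward(dlogits)
        dskips = [None] * d
        for j in reversed(range(d)):
            i = d - 1 - j
            dh = self.dec_blocks[j].backward(dh)
            n_up = dh.shape[1] - self._skip_channels[i]
            dh, dskips[i] = dh[:, :n_up], dh[:, n_up:]
            dh = self.ups[j].backward(dh)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc_blocks[i].backward(dh)
        return dh

    def predict_proba(self, x):
        """Inference-mode probabilities (dropout off) for (B, 1, H, W)."""
        return sigmoid(self.forward_logits(x, train=False))

    # -- training step ------------------------------------------------------
    def dice_loss_backward(self, x, target, smooth: float = 1.0):
        """Forward in training mode, backprop 1 - soft_dice over the batch.

        Returns the batch soft-Dice.  Gradients are left on the layers for
        the optimizer to consume.
        """
        target = np.asarray(target, dtype=self.dtype)
        z = self.forward_logits(x, train=True)
        p = sigmoid(z)
        inter = float((p * target).sum())
        denom = float(p.sum() + target.sum())
        dice = (2.0 * inter + smooth) / (denom + smooth)
        if not np.isfinite(dice):
            raise FloatingPointError("non-finite soft-Dice in training step")
        # d(1-dice)/dp = -(2*t - dice) / (denom + smooth); then through sigmoid
        dp = -(2.0 * target - dice) / (denom + smooth)
        dz = (dp * p * (1.0 - p)).astype(self.dtype)
        self.backward(dz)
        return dice


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> UNet2D:
    """Construct a freshly initialized model from an architecture spec."""
    return UNet2D(spec, seed=seed, dtype=dtype)
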