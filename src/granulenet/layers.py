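"""NumPy forward-pass layer primitives for the residual backbone.

All activations are channel-last ``(H, W, C)`` float arrays; convolution
kernels are ``(kh, kw, C_in, C_out)``.  Padding follows the "same" convention
(total pad split low/high, the extra pixel on the high side), which is what
lands a 224x224 input exactly on the printed 56x56 stage-1 grid.

Only inference is implemented: batch-norm layers carry frozen statistics
folded into a per-channel affine ``scale * x + shift``, so extracted features
are bit-reproducible for a fixed set of weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

__all__ = [
    "Conv2D",
    "BatchNorm",
    "conv2d",
    "relu",
    "max_pool",
    "same_pad_amounts",
]


def same_pad_amounts(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """Low/high padding so output size is ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1,
           padding: str = "same") -> np.ndarray:
    """2-D convolution (cross-correlation) of a (H, W, Cin) activation.

    Implemented as a strided window view contracted against the kernel with
    a single BLAS call, which keeps the full 224x224 backbone forward pass
    in the seconds range on one CPU.
    """
    if x.ndim != 3:
        raise ShapeError(f"conv2d expects (H, W, C) input, got shape {x.shape}")
    kh, kw, cin, _ = w.shape
    if x.shape[2] != cin:
        raise ShapeError(
            f"conv2d channel mismatch: input has {x.shape[2]} channels, "
            f"kernel expects {cin}")
    if padding == "same":
        ph = same_pad_amounts(x.shape[0], kh, stride)
        pw = same_pad_amounts(x.shape[1], kw, stride)
    elif padding == "valid":
        ph = pw = (0, 0)
    else:
        raise ShapeError(f"unknown padding mode {padding!r}")
    xp = np.pad(x, (ph, pw, (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(0, 1))[::stride, ::stride]
    # win: (H', W', C, kh, kw); contract (kh, kw, C) against kernel axes.
    return np.tensordot(win, w, axes=([3, 4, 2], [0, 1, 2]))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def max_pool(x: np.ndarray, kernel: int = 3, stride: int = 2,
             padding: str = "same") -> np.ndarray:
    if padding == "same":
        ph = same_pad_amounts(x.shape[0], kernel, stride)
        pw = same_pad_amounts(x.shape[1], kernel, stride)
    else:
        ph = pw = (0, 0)
    xp = np.pad(x, (ph, pw, (0, 0)), constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(0, 1))[::stride, ::stride]
    return win.max(axis=(3, 4))


@dataclass
class Conv2D:
    """Convolution layer with explicit kernel (no bias; a BatchNorm follows)."""

    w: np.ndarray  # (kh, kw, cin, cout)
    stride: int = 1
    padding: str = "same"

    @classmethod
    def he_init(cls, kh: int, kw: int, cin: int, cout: int,
                rng: np.random.Generator, stride: int = 1,
                padding: str = "same") -> "Conv2D":
        std = np.sqrt(2.0 / (kh * kw * cin))
        w = rng.normal(0.0, std, size=(kh, kw, cin, cout)).astype(np.float64)
        return cls(w=w, stride=stride, padding=padding)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return conv2d(x, self.w, stride=self.stride, padding=self.padding)


@dataclass
class BatchNorm:
    """Frozen-statistics batch normalisation, folded to ``scale*x + shift``.

    ``identity()`` gives an exact pass-through (scale 1, shift 0), used for
    the algebraic block tests and as the default random-init configuration.
    """

    scale: np.ndarray  # (C,)
    shift: np.ndarray  # (C,)

    @classmethod
    def identity(cls, channels: int) -> "BatchNorm":
        return cls(scale=np.ones(channels), shift=np.zeros(channels))

    @classmethod
    def from_moments(cls, gamma: np.ndarray, beta: np.ndarray,
                     mean: np.ndarray, var: np.ndarray,
                     eps: float = 1e-5) -> "BatchNorm":
        inv = gamma / np.sqrt(var + eps)
        return cls(scale=inv, shift=beta - mean * inv)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.scale.shape[0]:
            raise ShapeError(
                f"batch-norm channel mismatch: {x.shape[-1]} vs {self.scale.shape[0]}")
        return x * self.scale + self.shift
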