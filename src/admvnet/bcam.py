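"""Bilinear Contextual Attention Module.

Each modality's top-stage map is gated by a channel attention built from
local- and global-average-pooled descriptors (1D convolutions over the
channel axis, sigmoid weights, learnable local/global mixing).  Gated maps
are reduced to (c4, da^2) pooled descriptors; pairwise per-channel outer
products capture cross-modal correlation patterns, the three interaction
tensors are summed, sum-pooled over both interaction axes and
L2-normalized into the latent fusion vector F_b.

The attention logits are computed on per-sample channel-standardized
descriptors, so the gate responds to the pattern across channels rather
than overall intensity; together with the bilinear form's homogeneity this
makes F_b invariant to positive rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import core
from .nn.core import Tensor


@dataclass
class BCAMConfig:
    da: int = 4
    lap_window: int = 2
    conv1d_kernel: int = 3

    def __post_init__(self):
        if self.conv1d_kernel != 3:
            raise ValueError("the channel conv is implemented for kernel 3")


def _standardize_channels(x: Tensor, eps: float = 1e-12) -> Tensor:
    mu = core.tmean(x, axis=1, keepdims=True)
    var = core.tmean((x - mu) ** 2.0, axis=1, keepdims=True)
    return (x - mu) / core.sqrt(var + eps)


class ChannelAttention(nn.Module):
    def __init__(self, cfg: BCAMConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.taps_local = nn.Parameter((rng.standard_normal(3) * 0.5).astype(dtype))
        self.taps_global = nn.Parameter((rng.standard_normal(3) * 0.5).astype(dtype))
        self.alpha_raw = nn.Parameter(np.zeros((), dtype=dtype))  # sigmoid -> 0.5

    @staticmethod
    def _conv1d_channels(x: Tensor, taps: Tensor) -> Tensor:
        """Kernel-3 convolution along the channel axis, zero-padded."""
        c = x.shape[1]
        up = core.pad(x[:, 1:], ((0, 0), (0, 1)) + ((0, 0),) * (x.ndim - 2))
        down = core.pad(x[:, :-1], ((0, 0), (1, 0)) + ((0, 0),) * (x.ndim - 2))
        return taps[0] * down + taps[1] * x + taps[2] * up

    def attention_map(self, x: Tensor) -> Tensor:
        spatial = x.shape[2:]
        lw = self.cfg.lap_window
        lap_dims = tuple(-(-s // lw) for s in spatial)
        lap = core.adaptive_avg_pool3d(x, lap_dims)
        gap = core.tmean(x, axis=(2, 3, 4), keepdims=True)
        att_local = core.sigmoid(self._conv1d_channels(_standardize_channels(lap),
                                                       self.taps_local))
        att_global = core.sigmoid(self._conv1d_channels(_standardize_channels(gap),
                                                        self.taps_global))
        alpha = core.sigmoid(self.alpha_raw)
        att_local_up = core.interpolate3d(att_local, spatial)
        return alpha * att_local_up + (1.0 - alpha) * att_global

    def forward(self, x: Tensor, att_override=None) -> Tensor:
        if att_override is not None:
            return x * att_override
        return x * self.attention_map(x)


def pooled_descriptor(x: Tensor, da: int) -> Tensor:
    """Adaptive average pooling to a (da, da, 1) grid, flattened to
    (B, C, da^2) columns."""
    b, c = x.shape[:2]
    pooled = core.adaptive_avg_pool3d(x, (da, da, 1))
    return pooled.reshape((b, c, da * da))


def outer_fuse(a: Tensor, b: Tensor) -> Tensor:
    """Per-channel outer product: H[b,c,i,j] = a[b,c,i] * b[b,c,j]."""
    if a.shape != b.shape:
        raise ValueError(f"descriptor shapes differ: {a.shape} vs {b.shape}")
    bs, c, n = a.shape
    return a.reshape((bs, c, n, 1)) * b.reshape((bs, c, 1, n))


class BilinearContextualAttention(nn.Module):
    def __init__(self, cfg: BCAMConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.att_p = ChannelAttention(cfg, rng, dtype=dtype)
        self.att_g = ChannelAttention(cfg, rng, dtype=dtype)
        self.att_w = ChannelAttention(cfg, rng, dtype=dtype)

    def forward(self, hp4: Tensor, hg4: Tensor, hw4: Tensor, att_override=None):
        """Returns (F_b, degenerate) where F_b is (B, c4) with unit L2 norm
        per row, and degenerate is a boolean (B,) mask marking rows whose
        pre-normalization vector was exactly zero (left as zeros)."""
        da = self.cfg.da
        dp = pooled_descriptor(self.att_p(hp4, att_override), da)
        dg = pooled_descriptor(self.att_g(hg4, att_override), da)
        dw = pooled_descriptor(self.att_w(hw4, att_override), da)
        h = outer_fuse(dp, dg) + outer_fuse(dg, dw) + outer_fuse(dp, dw)
        v = core.tsum(h, axis=(2, 3))  # sum-pool both interaction axes -> (B, c4)
        sq = core.tsum(v * v, axis=1, keepdims=True)
        degenerate = (sq.data.reshape(-1) == 0.0)
        safe = core.sqrt(sq + Tensor(degenerate.reshape(-1, 1).astype(v.dtype)))
        fb = v / safe
        if degenerate.any():
            fb = fb * Tensor((~degenerate).reshape(-1, 1).astype(v.dtype))
        return fb, degenerate
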