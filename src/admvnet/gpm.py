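"""Global Perception Module: attention-based fusion of top-stage features.

Each modality's stage-4 map is refined by multi-head self-attention whose
key/value streams are pre-mixed by a depthwise-separable 3D convolution
(convolutional position mixing; no positional-encoding table).  Modalities
are then chained through a parameter-free multimodal normalizer that
removes, within each batch, the linear predictability of one modality's
features from the previous one (a ridge-regularized least-squares
projection — no learnable parameters).  A window-attention branch over the
summed modalities counteracts distribution shift between branches.  The
four streams are summed, passed through a feed-forward network, and
average-pooled into the global fusion vector F_g of length c4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import core
from .nn.core import Tensor


@dataclass
class GPMConfig:
    n_heads: int = 4
    window: tuple = (2, 2, 2)
    ridge: float = 1e-4
    ffn_hidden: int | None = None  # defaults to 2 * c4


def _to_tokens(x: Tensor) -> Tensor:
    """(B, C, D, H, W) -> (B, N, C) token matrix."""
    b, c = x.shape[:2]
    return x.reshape((b, c, -1)).transpose((0, 2, 1))


def _to_map(tokens: Tensor, spatial) -> Tensor:
    b, n, c = tokens.shape
    return tokens.transpose((0, 2, 1)).reshape((b, c) + tuple(spatial))


def _split_heads(t: Tensor, n_heads: int) -> Tensor:
    b, n, c = t.shape
    return t.reshape((b, n, n_heads, c // n_heads)).transpose((0, 2, 1, 3))


def _merge_heads(t: Tensor) -> Tensor:
    b, h, n, d = t.shape
    return t.transpose((0, 2, 1, 3)).reshape((b, n, h * d))


def _attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    scale = 1.0 / np.sqrt(q.shape[-1])
    scores = (q @ core.swap_last2(k)) * scale
    return core.softmax(scores, axis=-1) @ v


class MultiHeadAttention3d(nn.Module):
    """Shallow conv -> MHA over voxels with DWConv-mixed keys/values."""

    def __init__(self, channels: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if channels % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide channels={channels}")
        self.n_heads = n_heads
        self.shallow = nn.Conv3d(channels, channels, 3, rng, padding=1, dtype=dtype)
        self.dw = nn.DepthwiseSeparableConv3d(channels, 3, rng, dtype=dtype)
        self.wq = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wk = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wv = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wo = nn.Linear(channels, channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.shape[2:]
        f = self.shallow(x)
        kv = self.dw(f)
        q = _split_heads(self.wq(_to_tokens(f)), self.n_heads)
        k = _split_heads(self.wk(_to_tokens(kv)), self.n_heads)
        v = _split_heads(self.wv(_to_tokens(kv)), self.n_heads)
        out = self.wo(_merge_heads(_attention(q, k, v)))
        return _to_map(out, spatial)


class RegBNAligner(nn.Module):
    """Batchwise ridge projection: returns g minus its least-squares
    prediction from f.  No learnable parameters; the projection coefficients
    are batch statistics (refit each training batch, frozen at eval)."""

    def __init__(self, ridge: float = 1e-4):
        super().__init__()
        self.ridge = ridge
        self._buffers = {"coef": np.zeros((0, 0), dtype=np.float32),
                         "f_mean": np.zeros(0, dtype=np.float32),
                         "g_mean": np.zeros(0, dtype=np.float32)}

    def forward(self, f: Tensor, g: Tensor) -> Tensor:
        if f.shape != g.shape:
            raise ValueError("modality feature shapes must match")
        b = f.shape[0]
        d = int(np.prod(f.shape[1:]))
        f_flat = f.reshape((b, d))
        g_flat = g.reshape((b, d))
        if self.training:
            if b < 2:
                warnings.warn("RegBN needs batch >= 2; passing features through")
                return g
            fm = f_flat.data.astype(np.float64)
            gm = g_flat.data.astype(np.float64)
            f_mean = fm.mean(axis=0)
            g_mean = gm.mean(axis=0)
            fc = fm - f_mean
            gc = gm - g_mean
            gram = fc.T @ fc + self.ridge * np.eye(d)
            coef = np.linalg.solve(gram, fc.T @ gc)
            self._buffers["coef"] = coef.astype(np.float32)
            self._buffers["f_mean"] = f_mean.astype(np.float32)
            self._buffers["g_mean"] = g_mean.astype(np.float32)
        else:
            coef = self._buffers["coef"]
            if coef.shape != (d, d):
                warnings.warn("RegBN has no fitted statistics; passing features through")
                return g
            f_mean = self._buffers["f_mean"]
            g_mean = self._buffers["g_mean"]
        dt = f.dtype
        resid = (g_flat - Tensor(g_mean.astype(dt))
                 - (f_flat - Tensor(f_mean.astype(dt))) @ Tensor(coef.astype(dt)))
        return resid.reshape(g.shape)


class WindowAttention3d(nn.Module):
    """Self-attention computed independently in non-overlapping windows."""

    def __init__(self, channels: int, window: tuple, n_heads: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if channels % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide channels={channels}")
        self.window = tuple(window)
        self.n_heads = n_heads
        self.wq = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wk = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wv = nn.Linear(channels, channels, rng, dtype=dtype)
        self.wo = nn.Linear(channels, channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[:2]
        spatial = x.shape[2:]
        win = tuple(min(w, s) for w, s in zip(self.window, spatial))
        pads = [(0, 0), (0, 0)] + [(0, (-s) % w) for s, w in zip(spatial, win)]
        xp = core.pad(x, tuple(pads)) if any(p[1] for p in pads) else x
        pd, ph, pw = xp.shape[2:]
        nd, nh, nw = pd // win[0], ph // win[1], pw // win[2]
        t = xp.reshape((b, c, nd, win[0], nh, win[1], nw, win[2]))
        t = t.transpose((0, 2, 4, 6, 3, 5, 7, 1))
        t = t.reshape((b * nd * nh * nw, win[0] * win[1] * win[2], c))
        q = _split_heads(self.wq(t), self.n_heads)
        k = _split_heads(self.wk(t), self.n_heads)
        v = _split_heads(self.wv(t), self.n_heads)
        out = self.wo(_merge_heads(_attention(q, k, v)))
        out = out.reshape((b, nd, nh, nw, win[0], win[1], win[2], c))
        out = out.transpose((0, 7, 1, 4, 2, 5, 3, 6)).reshape((b, c, pd, ph, pw))
        return out[:, :, :spatial[0], :spatial[1], :spatial[2]]


class GlobalPerceptionModule(nn.Module):
    def __init__(self, c4: int, cfg: GPMConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        hidden = cfg.ffn_hidden or 2 * c4
        self.mha_g = MultiHeadAttention3d(c4, cfg.n_heads, rng, dtype=dtype)
        self.mha_w = MultiHeadAttention3d(c4, cfg.n_heads, rng, dtype=dtype)
        self.mha_p = MultiHeadAttention3d(c4, cfg.n_heads, rng, dtype=dtype)
        self.regbn_w = RegBNAligner(cfg.ridge)
        self.regbn_p = RegBNAligner(cfg.ridge)
        self.wa = WindowAttention3d(c4, cfg.window, cfg.n_heads, rng, dtype=dtype)
        self.ffn1 = nn.Linear(c4, hidden, rng, dtype=dtype)
        self.ffn2 = nn.Linear(hidden, c4, rng, dtype=dtype)

    def forward(self, hg4: Tensor, hw4: Tensor, hp4: Tensor) -> Tensor:
        """Returns the global fusion vector F_g of shape (B, c4)."""
        hg_p = self.mha_g(hg4)
        hw_p = self.regbn_w(hg_p, self.mha_w(hw4))
        hp_p = self.regbn_p(hw_p, self.mha_p(hp4))
        wsum = self.wa(hg4 + hw4 + hp4)
        s = hg_p + hw_p + hp_p + wsum
        tokens = _to_tokens(s)
        out = self.ffn2(core.relu(self.ffn1(tokens)))
        return core.tmean(out, axis=1)
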