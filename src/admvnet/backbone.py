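"""Hybrid-convolution backbone with a diffusion-guided boundary path.

Each stage combines three parallel pathways:

* a standard convolution path (SCP): conv -> BN -> ReLU stacks that build
  the receptive field and carry global semantics;
* a semantic-difference-guided diffusion path (SDP): an explicit nonlinear
  anisotropic diffusion process on the stage's pre-features.  For voxel p
  with face neighbors pe,

      Fhat_p = sum_pe h(||G_pe - G_p||^2) * (F_pe - F_p)
      F      <- lambda * F + nu * Fhat            (T iterations)

  where G is a semantic guide produced by a down/up-sampled branch and
  h(.) is a learnable nonnegative scalar map, so diffusion is damped across
  strong semantic boundaries (edge-preserving smoothing);
* a direct mapping path (1x1x1 projection) that preserves the input.

The SCP and SDP outputs are fused by a learned per-channel sigmoid gate and
added to the direct path.  Four stages, each halving the spatial dims,
yield the per-modality feature hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import core
from .nn.core import Tensor

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (32, 64, 128, 256)


@dataclass
class HCNetStageConfig:
    in_channels: int
    out_channels: int
    downsample: bool = True
    diffusion_steps: int = 2
    lambda_init: float = 1.0
    nu_init: float = 0.1

    def __post_init__(self):
        if self.diffusion_steps < 0:
            raise ValueError("diffusion_steps must be >= 0")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")


class DiffusivityMap(nn.Module):
    """Learnable nonnegative scalar map h(u) for the diffusion weights.

    A two-layer perceptron on the squared guide difference with a softplus
    output (nonnegativity makes the update diffusion-like) scaled by a
    squared gain; zeroing ``gain`` switches the diffusion term off exactly.
    """

    def __init__(self, rng: np.random.Generator, hidden: int = 4, dtype=np.float32):
        super().__init__()
        self.w1 = nn.Parameter((rng.standard_normal((1, hidden)) * 0.5).astype(dtype))
        self.b1 = nn.Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = nn.Parameter((rng.standard_normal((hidden, 1)) * 0.5).astype(dtype))
        self.b2 = nn.Parameter(np.zeros(1, dtype=dtype))
        self.gain = nn.Parameter(np.ones((), dtype=dtype))

    def forward(self, u: Tensor) -> Tensor:
        shape = u.shape
        flat = u.reshape((-1, 1))
        z = core.tanh(flat @ self.w1 + self.b1)
        out = core.softplus(z @ self.w2 + self.b2)
        return (self.gain * self.gain) * out.reshape(shape)


def sdp_diffuse(f0: Tensor, guide: Tensor, h: DiffusivityMap,
                lam: Tensor, nu: Tensor, steps: int) -> Tensor:
    """Run ``steps`` iterations of guided diffusion on ``f0``.

    Neighborhood: 6-connected faces; zero-flux boundary (edges with no
    neighbor contribute nothing).  The guide and hence the edge weights are
    fixed across iterations.
    """
    if f0.shape != guide.shape:
        raise ValueError(f"feature/guide shape mismatch: {f0.shape} vs {guide.shape}")
    # per-axis edge weights from squared channel-norm of guide differences
    weights = []
    for axis in (2, 3, 4):
        sl_hi = [slice(None)] * 5
        sl_lo = [slice(None)] * 5
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        gdiff = guide[tuple(sl_hi)] - guide[tuple(sl_lo)]
        u = core.tsum(gdiff * gdiff, axis=1, keepdims=True)
        weights.append(h(u))

    f = f0
    for _ in range(steps):
        fhat = None
        for i, axis in enumerate((2, 3, 4)):
            sl_hi = [slice(None)] * 5
            sl_lo = [slice(None)] * 5
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            d = f[tuple(sl_hi)] - f[tuple(sl_lo)]
            wd = weights[i] * d
            pad_lo = [(0, 0)] * 5
            pad_hi = [(0, 0)] * 5
            pad_lo[axis] = (0, 1)   # contribution at the lower voxel of each edge
            pad_hi[axis] = (1, 0)   # contribution at the upper voxel (sign flipped)
            term = core.pad(wd, tuple(pad_lo)) - core.pad(wd, tuple(pad_hi))
            fhat = term if fhat is None else fhat + term
        f = lam * f + nu * fhat
    return f


class HCNetStage(nn.Module):
    def __init__(self, cfg: HCNetStageConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        s = 2 if cfg.downsample else 1
        c = cfg.out_channels
        self.conv1 = nn.Conv3d(cfg.in_channels, c, 3, rng, stride=s, padding=1, dtype=dtype)
        self.bn1 = nn.BatchNorm3d(c, dtype=dtype)
        self.conv2 = nn.Conv3d(c, c, 3, rng, stride=1, padding=1, dtype=dtype)
        self.bn2 = nn.BatchNorm3d(c, dtype=dtype)
        self.guide_conv = nn.Conv3d(c, c, 1, rng, stride=1, padding=0, dtype=dtype)
        self.h = DiffusivityMap(rng, dtype=dtype)
        self.lam = nn.Parameter(np.asarray(cfg.lambda_init, dtype=dtype))
        self.nu = nn.Parameter(np.asarray(cfg.nu_init, dtype=dtype))
        self.gate_fc = nn.Linear(2 * c, c, rng, dtype=dtype)
        self.proj = nn.Conv3d(cfg.in_channels, c, 1, rng, stride=s, padding=0, dtype=dtype)

    # -- pathways ------------------------------------------------------------
    def pre_features(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        return core.relu(self.bn1(self.conv1(x)))

    def scp_forward(self, x: Tensor) -> Tensor:
        """Standard convolution path: conv-BN-ReLU x2 (stride on the first)."""
        return core.relu(self.bn2(self.conv2(self.pre_features(x))))

    def semantic_guide(self, pre: Tensor) -> Tensor:
        """Semantic guide G: downsample-by-2 conv, then resize back.

        Small spatial dims (< 4) skip the down/up round trip — resizing a
        1-voxel grid back up would make G spatially constant and kill the
        guidance signal (documented fallback).
        """
        spatial = pre.shape[2:]
        if min(spatial) < 4:
            return core.relu(self.guide_conv(pre))
        g = core.relu(self.guide_conv(pre[:, :, ::2, ::2, ::2]))
        return core.interpolate3d(g, spatial)

    def forward(self, x: Tensor, gate_override: float | None = None) -> Tensor:
        pre = self.pre_features(x)
        scp = core.relu(self.bn2(self.conv2(pre)))
        guide = self.semantic_guide(pre)
        sdp = sdp_diffuse(pre, guide, self.h, self.lam, self.nu,
                          self.cfg.diffusion_steps)
        if gate_override is None:
            pooled = core.concat([
                core.tmean(scp, axis=(2, 3, 4)),
                core.tmean(sdp, axis=(2, 3, 4))], axis=1)
            gate = core.sigmoid(self.gate_fc(pooled))
            gate = gate.reshape((gate.shape[0], gate.shape[1], 1, 1, 1))
        else:
            gate = Tensor(np.full((1, 1, 1, 1, 1), gate_override, dtype=x.dtype))
        return gate * scp + (1.0 - gate) * sdp + self.proj(x)


class HCNetBackbone(nn.Module):
    """Four-stage per-modality feature extractor."""

    def __init__(self, widths=DEFAULT_WIDTHS, in_channels: int = 1,
                 diffusion_steps: int = 2, lambda_init: float = 1.0,
                 nu_init: float = 0.1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.widths = tuple(widths)
        chans = (in_channels,) + self.widths
        self.stages = nn.ModuleList([
            HCNetStage(HCNetStageConfig(chans[i], chans[i + 1], downsample=True,
                                        diffusion_steps=diffusion_steps,
                                        lambda_init=lambda_init, nu_init=nu_init),
                       rng, dtype=dtype)
            for i in range(4)
        ])

    def forward(self, x: Tensor) -> list[Tensor]:
        x = pad_to_multiple(x, 16)
        maps = []
        for stage in self.stages:
            x = stage(x)
            maps.append(x)
        return maps


def pad_to_multiple(x: Tensor, m: int) -> Tensor:
    """Zero-pad trailing spatial dims up to a multiple of ``m``."""
    spatial = x.shape[2:]
    pads = [(0, 0), (0, 0)]
    needed = False
    for s in spatial:
        extra = (-s) % m
        pads.append((0, extra))
        needed = needed or extra > 0
    if not needed:
        return x
    logger.warning("input spatial shape %s not divisible by %d; zero-padding to %s",
                   tuple(spatial), m, tuple(s + p[1] for s, p in zip(spatial, pads[2:])))
    return core.pad(x, tuple(pads))
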