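"""Multi-level Local Cross-modal Aggregation.

The cross-modal sums of backbone stages 1-3 are projected into a common
channel space, refined by a bidirectional (top-down then bottom-up) pass of
cross-scale weighted fusion nodes, pooled to a fixed 4x4x4 grid,
concatenated and projected to the local fusion vector F_m.

Each fusion node computes the normalized weighted combination

    F_out = sum_i w_i * U(F_i) / (sum_i w_i + eps)

with learnable nonnegative weights w_i (rectified parameterization) and
resampling U (trilinear up / learnable strided-conv down), followed by a
pointwise conv + ReLU refinement so nodes are not purely affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import core
from .nn.core import Tensor


@dataclass
class MLCAConfig:
    aligned_channels: int = 128
    eps: float = 1e-4
    pooled_size: int = 4


class WeightedFusionNode(nn.Module):
    def __init__(self, n_inputs: int, channels: int, rng: np.random.Generator,
                 eps: float = 1e-4, allow_down: bool = True, dtype=np.float32):
        super().__init__()
        if n_inputs < 1:
            raise ValueError("a fusion node needs at least one input")
        self.raw_w = nn.Parameter(np.ones(n_inputs, dtype=dtype))
        self.eps = eps
        # the strided-conv downsampler is only instantiated for nodes whose
        # wiring can feed them a finer map (keeps every parameter trainable)
        self.down = (nn.Conv3d(channels, channels, 2, rng, stride=2, dtype=dtype)
                     if allow_down else None)
        self.refine = nn.Conv3d(channels, channels, 1, rng, dtype=dtype)

    @property
    def weights(self) -> Tensor:
        return core.relu(self.raw_w)

    def set_weights(self, values):
        """Set the effective (nonnegative) weights directly."""
        self.raw_w.data = np.asarray(values, dtype=self.raw_w.dtype)

    def resample(self, x: Tensor, target_shape) -> Tensor:
        target = tuple(target_shape)
        if self.down is not None:
            while all(s >= 2 * t for s, t in zip(x.shape[2:], target)):
                x = self.down(x)
        if tuple(x.shape[2:]) != target:
            x = core.interpolate3d(x, target)
        return x

    def combine(self, resampled: list[Tensor]) -> Tensor:
        """The normalized weighted sum (pre-refinement node output)."""
        if not resampled:
            raise ValueError("empty input list")
        w = self.weights
        num = None
        for i, x in enumerate(resampled):
            term = w[i] * x
            num = term if num is None else num + term
        den = core.tsum(w) + self.eps
        return num / den

    def forward(self, inputs: list[Tensor], target_shape) -> Tensor:
        pre = self.combine([self.resample(x, target_shape) for x in inputs])
        return core.relu(self.refine(pre))


class MLCAModule(nn.Module):
    def __init__(self, stage_channels, c4: int, cfg: MLCAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        a = cfg.aligned_channels
        self.cfg = cfg
        self.align = nn.ModuleList([
            nn.Conv3d(c, a, 1, rng, dtype=dtype) for c in stage_channels])
        self.td2 = WeightedFusionNode(2, a, rng, eps=cfg.eps, allow_down=False, dtype=dtype)
        self.td1 = WeightedFusionNode(2, a, rng, eps=cfg.eps, allow_down=False, dtype=dtype)
        self.bu2 = WeightedFusionNode(3, a, rng, eps=cfg.eps, dtype=dtype)
        self.bu3 = WeightedFusionNode(2, a, rng, eps=cfg.eps, dtype=dtype)
        p = cfg.pooled_size
        self.out_proj = nn.Linear(3 * a * p ** 3, c4, rng, dtype=dtype)

    def align_channels(self, h1: Tensor, h2: Tensor, h3: Tensor):
        return tuple(conv(h) for conv, h in zip(self.align, (h1, h2, h3)))

    def forward(self, h1: Tensor, h2: Tensor, h3: Tensor) -> Tensor:
        """h1..h3: cross-modal per-stage sums at their native scales
        (fine to coarse).  Returns F_m of shape (B, c4)."""
        a1, a2, a3 = self.align_channels(h1, h2, h3)
        # top-down (coarse -> fine)
        td3 = a3
        td2 = self.td2([a2, td3], a2.shape[2:])
        td1 = self.td1([a1, td2], a1.shape[2:])
        # bottom-up (fine -> coarse)
        o1 = td1
        o2 = self.bu2([a2, td2, o1], a2.shape[2:])
        o3 = self.bu3([a3, o2], a3.shape[2:])
        p = self.cfg.pooled_size
        pooled = [core.adaptive_avg_pool3d(o, (p, p, p)) for o in (o1, o2, o3)]
        flat = core.concat([t.reshape((t.shape[0], -1)) for t in pooled], axis=1)
        return self.out_proj(flat)
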