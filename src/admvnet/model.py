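"""End-to-end assembly: three modality backbones, the three fusion views,
a fused classifier head and the ROI-weighting branch.

Volumes flow through weight-independent HCNet backbones (GM, WM, PET);
their stage-4 maps feed the global (GPM) and latent (BCAM) views and the
stage-1..3 cross-modal sums feed the local view (MLCA).  The three view
vectors are concatenated, projected to c4 (F_c), classified to the
multimodal logits y_c, and refined by the ROI branch into the final logits
y_hat.  Any view can be ablated, replacing its vector with zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .backbone import HCNetBackbone
from .bcam import BCAMConfig, BilinearContextualAttention
from .gpm import GPMConfig, GlobalPerceptionModule
from .mlca import MLCAConfig, MLCAModule
from .nn import core
from .nn.core import Tensor
from .ripm import RegionalInterestModule, RIPMConfig

MODALITIES = ("gm", "wm", "pet")


@dataclass
class ModelConfig:
    widths: tuple = (32, 64, 128, 256)
    diffusion_steps: int = 2
    lambda_init: float = 1.0
    nu_init: float = 0.1
    gpm: GPMConfig = field(default_factory=GPMConfig)
    mlca: MLCAConfig = field(default_factory=MLCAConfig)
    bcam: BCAMConfig = field(default_factory=BCAMConfig)
    ripm: RIPMConfig = field(default_factory=RIPMConfig)
    use_gpm: bool = True
    use_mlca: bool = True
    use_bcam: bool = True
    use_ripm: bool = True
    n_classes: int = 2
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.widths = tuple(self.widths)
        if isinstance(self.gpm, dict):
            self.gpm = GPMConfig(**self.gpm)
        if isinstance(self.mlca, dict):
            self.mlca = MLCAConfig(**self.mlca)
        if isinstance(self.bcam, dict):
            self.bcam = BCAMConfig(**self.bcam)
        if isinstance(self.ripm, dict):
            self.ripm = RIPMConfig(**self.ripm)
        if isinstance(self.gpm.window, list):
            self.gpm.window = tuple(self.gpm.window)

    @property
    def c4(self) -> int:
        return self.widths[-1]

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Desk-scale configuration used by the synthetic experiments."""
        kwargs = dict(widths=(8, 16, 32, 64),
                      gpm=GPMConfig(n_heads=4),
                      mlca=MLCAConfig(aligned_channels=32),
                      seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class ADMVNet(nn.Module):
    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c4 = cfg.c4
        self.backbones = nn.ModuleList([
            HCNetBackbone(cfg.widths, diffusion_steps=cfg.diffusion_steps,
                          lambda_init=cfg.lambda_init, nu_init=cfg.nu_init,
                          rng=rng, dtype=dtype)
            for _ in MODALITIES])
        if cfg.use_gpm:
            self.gpm = GlobalPerceptionModule(c4, cfg.gpm, rng, dtype=dtype)
        if cfg.use_mlca:
            self.mlca = MLCAModule(cfg.widths[:3], c4, cfg.mlca, rng, dtype=dtype)
        if cfg.use_bcam:
            self.bcam = BilinearContextualAttention(cfg.bcam, rng, dtype=dtype)
        self.fuse = nn.Linear(3 * c4, c4, rng, dtype=dtype)
        self.drop = nn.Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 1))
        # small head initialization keeps initial logits O(1) for stable warm-up
        self.head = nn.Linear(c4, cfg.n_classes, rng, init_scale=0.1, dtype=dtype)
        if cfg.use_ripm:
            self.ripm = RegionalInterestModule(cfg.ripm, rng, dtype=dtype)

    # -- pieces --------------------------------------------------------------
    def fuse_views(self, fg: Tensor, fm: Tensor, fb: Tensor) -> Tensor:
        for name, v in (("F_g", fg), ("F_m", fm), ("F_b", fb)):
            if v.shape[-1] != self.cfg.c4:
                raise ValueError(f"{name} has length {v.shape[-1]}, expected {self.cfg.c4}")
        return core.relu(self.fuse(core.concat([fg, fm, fb], axis=1)))

    def classify(self, fc: Tensor) -> Tensor:
        return self.head(self.drop(fc))

    # -- forward -------------------------------------------------------------
    def forward(self, gm, wm, pet, roi_profile=None, ablate=()) -> dict:
        """gm/wm/pet: (B, D, H, W) arrays or Tensors; roi_profile: (B, 90, 3).

        ``ablate`` may contain "gpm", "mlca", "bcam", "ripm" to switch a
        component off for this pass (its view vector becomes zeros).
        """
        vols = []
        for v in (gm, wm, pet):
            t = v if isinstance(v, Tensor) else Tensor(np.asarray(v))
            if t.ndim == 4:
                t = t.reshape((t.shape[0], 1) + t.shape[1:])
            vols.append(t)
        b = vols[0].shape[0]
        hier = {m: bb(v) for m, bb, v in zip(MODALITIES, self.backbones, vols)}
        self._check_finite(hier)
        stage4 = {m: hier[m][3] for m in MODALITIES}
        sums = [hier["gm"][s] + hier["wm"][s] + hier["pet"][s] for s in range(3)]

        c4 = self.cfg.c4
        dtype = vols[0].dtype
        zeros = Tensor(np.zeros((b, c4), dtype=dtype))
        use = {m: getattr(self.cfg, f"use_{m}") and m not in ablate
               for m in ("gpm", "mlca", "bcam", "ripm")}
        fg = self.gpm(stage4["gm"], stage4["wm"], stage4["pet"]) if use["gpm"] else zeros
        fm = self.mlca(*sums) if use["mlca"] else zeros
        if use["bcam"]:
            fb, degenerate = self.bcam(stage4["pet"], stage4["gm"], stage4["wm"])
        else:
            fb, degenerate = zeros, np.zeros(b, dtype=bool)
        fc = self.fuse_views(fg, fm, fb)
        y_c = self.classify(fc)

        out = {"y_c": y_c, "views": {"fg": fg, "fm": fm, "fb": fb},
               "bcam_degenerate": degenerate, "hierarchy": hier}
        if use["ripm"]:
            prof = None
            if roi_profile is not None:
                prof = roi_profile if isinstance(roi_profile, Tensor) else Tensor(
                    np.asarray(roi_profile, dtype=dtype))
            ripm_out = self.ripm(y_c, roi_profile=prof)
            out.update({"y_hat": ripm_out["y_hat"], "omega": ripm_out["omega"],
                        "importance": ripm_out["importance"],
                        "y_cr": ripm_out["y_cr"]})
        else:
            out["y_hat"] = y_c
            out["omega"] = None
            out["importance"] = None
        if not np.all(np.isfinite(out["y_hat"].data)):
            raise FloatingPointError("non-finite logits out of the classifier head")
        return out

    @staticmethod
    def _check_finite(hier):
        for m, maps in hier.items():
            for s, t in enumerate(maps, start=1):
                if not np.all(np.isfinite(t.data)):
                    raise FloatingPointError(
                        f"non-finite values in backbone '{m}' stage {s}")

    # -- checkpointing -------------------------------------------------------
    def save(self, path):
        path = Path(path)
        state = self.state_dict()
        np.savez_compressed(path, **state)
        path.with_suffix(".config.json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path) -> "ADMVNet":
        path = Path(path)
        cfg_path = path.with_suffix(".config.json")
        cfg = ModelConfig(**json.loads(cfg_path.read_text()))
        model = cls(cfg)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
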