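"""Regional Interest Perception Module.

Maintains a 90-element brain-region weight vector omega, refined over t
iterations: ROI tokens derived from the classifier logits (and, when
available, per-region intensity profiles) are linearly mapped to query,
key and value vectors; omega modulates all three elementwise; a 90x90
row-stochastic attention matrix mixes the modulated values into a salient
region feature R_h; and a gated-recurrent cell updates omega from R_h.
After t rounds, R_h is mapped to an ROI logit pair y_cr that is fused with
the multimodal logits y_c through a learnable gate.  softmax(omega) is the
reported per-region importance.

Grounding: index i of omega corresponds to parcellation region i because
the R0 and hidden tokens receive region i's mean-intensity profile through
a learnable affine "deficit" encoding; the query/key/value maps and the
recurrent candidate are identity-initialized so region weights start out
driven by their own region's evidence and are then refined by training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import core
from .nn.core import Tensor

N_REGIONS = 90


@dataclass
class RIPMConfig:
    t: int = 7
    fusion_alpha_init: float = 0.0  # sigmoid -> 0.5
    n_regions: int = N_REGIONS
    n_classes: int = 2


class RegionalInterestModule(nn.Module):
    def __init__(self, cfg: RIPMConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        r = cfg.n_regions

        # identity plus a tiny symmetry-breaking perturbation: region tokens
        # start mapped to themselves, so omega's indices stay grounded
        def near_identity():
            return nn.Parameter((np.eye(r) + 1e-3 * rng.standard_normal((r, r))).astype(dtype))

        self.w_rq = near_identity()
        self.w_rk = near_identity()
        self.w_rv = near_identity()
        self.gru = nn.GRUCell(r, r, rng, dtype=dtype, candidate_identity=True)
        # the logit->ROI expansions start small so R0 is dominated by the
        # region-grounded profile term at the beginning of training
        self.to_r0 = nn.Linear(cfg.n_classes, r, rng, init_scale=0.01, dtype=dtype)
        self.to_hidden = nn.Linear(cfg.n_classes, r, rng, init_scale=0.01, dtype=dtype)
        # learnable affine "deficit" encoding of the per-region profiles
        # (expected on standardized intensities): a region token starts near
        # zero for cohort-typical tissue and grows with atrophy /
        # hypometabolism; training refines both weights and bias
        self.roi_mix = nn.Parameter(np.full((3, 1), -1.0, dtype=dtype))
        self.roi_bias = nn.Parameter(np.zeros((), dtype=dtype))
        self.roi_mix_h = nn.Parameter(np.full((3, 1), -1.0, dtype=dtype))
        self.roi_bias_h = nn.Parameter(np.zeros((), dtype=dtype))
        self.from_rh = nn.Linear(r, r, rng, dtype=dtype)
        self.to_logits = nn.Linear(r, cfg.n_classes, rng, init_scale=0.1, dtype=dtype)
        self.fusion_alpha = nn.Parameter(np.asarray(cfg.fusion_alpha_init, dtype=dtype))

    # -- stages --------------------------------------------------------------
    def init_state(self, y_c: Tensor, roi_profile: Tensor | None = None):
        """R0 and the hidden token from y_c (optionally region-grounded),
        plus the uniform all-ones initial weight vector."""
        b = y_c.shape[0]
        r0 = self.to_r0(y_c)
        y_hidden = self.to_hidden(y_c)
        if roi_profile is not None:
            shape = (b, self.cfg.n_regions)
            r0 = r0 + (roi_profile @ self.roi_mix).reshape(shape) + self.roi_bias
            y_hidden = (y_hidden + (roi_profile @ self.roi_mix_h).reshape(shape)
                        + self.roi_bias_h)
        omega0 = Tensor(np.ones((b, self.cfg.n_regions), dtype=y_c.dtype))
        return r0, y_hidden, omega0

    def step(self, omega: Tensor, r0: Tensor, y_hidden: Tensor):
        """One attention + gated-recurrent refinement of omega.

        Returns (R_h, omega_new, attention); attention rows sum to 1.
        """
        r = self.cfg.n_regions
        b = omega.shape[0]
        q = y_hidden @ self.w_rq
        k = r0 @ self.w_rk
        v = r0 @ self.w_rv
        wq = (omega * q).reshape((b, r, 1))
        wk = (omega * k).reshape((b, 1, r))
        scores = (wq * wk) * (1.0 / np.sqrt(r))
        att = core.softmax(scores, axis=-1)
        if not np.all(np.isfinite(att.data)):
            raise FloatingPointError(
                "non-finite ROI attention; omega range "
                f"[{omega.data.min():.3g}, {omega.data.max():.3g}], "
                f"score range [{scores.data.min():.3g}, {scores.data.max():.3g}]")
        rh = (att @ (omega * v).reshape((b, r, 1))).reshape((b, r))
        omega_new = self.gru(rh, omega)
        return rh, omega_new, att

    def forward(self, y_c: Tensor, roi_profile: Tensor | None = None,
                t: int | None = None) -> dict:
        t = self.cfg.t if t is None else t
        if t < 1:
            raise ValueError("iteration count t must be >= 1")
        r0, y_hidden, omega = self.init_state(y_c, roi_profile)
        rh = None
        for _ in range(t):
            rh, omega, att = self.step(omega, r0, y_hidden)
        r_tilde = self.from_rh(rh)
        y_cr = self.to_logits(r_tilde)
        y_hat = y_c + core.sigmoid(self.fusion_alpha) * y_cr
        return {
            "y_hat": y_hat,
            "y_cr": y_cr,
            "omega": omega,
            "importance": core.softmax(omega, axis=-1),
            "r_tilde": r_tilde,
            "attention": att,
        }


def export_roi_report(importance: np.ndarray,
                      region_names: list[str] | None = None) -> pd.DataFrame:
    """Ranked region-importance table.

    ``importance`` is the softmax weight vector (sums to 1).  Ties share a
    rank (competition ranking) and the table is ordered by descending
    weight with region_id as the stable tie-break.
    """
    importance = np.asarray(importance, dtype=float).reshape(-1)
    if importance.shape[0] != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} weights, got {importance.shape[0]}")
    ids = np.arange(1, N_REGIONS + 1)
    names = region_names if region_names is not None else [f"region_{i:02d}" for i in ids]
    from scipy.stats import rankdata
    ranks = rankdata(-importance, method="min").astype(int)
    df = pd.DataFrame({"region_id": ids, "name": names,
                       "weight": importance, "rank": ranks})
    return df.sort_values(["rank", "region_id"], kind="stable").reset_index(drop=True)
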