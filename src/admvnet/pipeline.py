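"""Training, cross-validation and the estimator/results interface.

`ADMVNetClassifier` follows the model/results convention of statistical
modelling packages: the estimator is built from a dataset and
configuration, `fit()` runs the optimisation and returns an
`ADMVNetResults` object carrying the trained network, the per-epoch log,
held-out metrics and the ROI-importance table, with a `summary()` view.
`cross_validate` and `t_sweep` provide the k-fold evaluation protocol
(stratified folds, per-fold metrics, mean +/- sd aggregates, paired
t-tests between configurations).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import nn
from .metrics import MetricsReport, compute_metrics
from .model import ADMVNet, ModelConfig
from .nn import core, optim
from .nn.core import Tensor
from .synthetic import MultimodalSample, ParcellationMap, regional_profile

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 16
    epochs: int = 40
    momentum: float = 0.9
    weight_decay: float = 1e-4
    clip_norm: float | None = 5.0  # global gradient-norm clipping
    aux_loss_weight: float = 0.3  # deep supervision on the trunk and ROI logits
    folds: int = 10
    seed: int = 0
    task: str = "synthetic"

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size, epochs must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale settings for the synthetic experiments."""
        kwargs = dict(lr=0.01, batch_size=8, epochs=10, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class VolumeDataset:
    """Stacked multimodal volumes plus per-region intensity profiles."""

    def __init__(self, samples: list[MultimodalSample], parcellation: ParcellationMap):
        self.parcellation = parcellation
        self.gm = np.stack([s.gm for s in samples]).astype(np.float32)
        self.wm = np.stack([s.wm for s in samples]).astype(np.float32)
        self.pet = np.stack([s.pet for s in samples]).astype(np.float32)
        self.labels = np.array([s.label for s in samples], dtype=int)
        self.subject_ids = [s.subject_id for s in samples]
        self.roi_profiles = np.stack([regional_profile(s) for s in samples])

    def __len__(self):
        return self.labels.shape[0]

    def standardize(self, stats: dict | None = None) -> tuple["VolumeDataset", dict]:
        """Per-modality z-scoring inside the brain mask (background stays 0).

        Without ``stats`` the mean/sd are estimated from this dataset (use
        the training split) and returned for reuse on held-out data.
        """
        mask = self.parcellation.mask
        vols = {"gm": self.gm, "wm": self.wm, "pet": self.pet}
        if stats is None:
            stats = {}
            for name, v in vols.items():
                inside = v[:, mask]
                stats[name] = (float(inside.mean()), float(inside.std()) or 1.0)
        out = object.__new__(VolumeDataset)
        out.parcellation = self.parcellation
        for name, v in vols.items():
            mu, sd = stats[name]
            z = np.zeros_like(v)
            z[:, mask] = (v[:, mask] - mu) / sd
            setattr(out, name, z)
        out.labels = self.labels.copy()
        out.subject_ids = list(self.subject_ids)
        sizes = self.parcellation.region_sizes.astype(np.float64)
        labels_flat = self.parcellation.labels.ravel()
        prof = np.empty_like(self.roi_profiles)
        for m, name in enumerate(("gm", "wm", "pet")):
            v = getattr(out, name).reshape(len(self), -1).astype(np.float64)
            sums = np.stack([np.bincount(labels_flat, weights=row, minlength=91)[1:]
                             for row in v])
            prof[:, :, m] = (sums / sizes).astype(np.float32)
        out.roi_profiles = prof
        return out, stats

    def subset(self, idx) -> "VolumeDataset":
        out = object.__new__(VolumeDataset)
        out.parcellation = self.parcellation
        idx = np.asarray(idx)
        out.gm, out.wm, out.pet = self.gm[idx], self.wm[idx], self.pet[idx]
        out.labels = self.labels[idx]
        out.subject_ids = [self.subject_ids[i] for i in idx]
        out.roi_profiles = self.roi_profiles[idx]
        return out

    def batch(self, idx):
        return (self.gm[idx], self.wm[idx], self.pet[idx],
                self.roi_profiles[idx], self.labels[idx])


def kfold_split(subject_ids, labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (one test-fold index per subject)."""
    labels = np.asarray(labels)
    n = len(subject_ids)
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    counts = np.bincount(labels)
    if counts.min() < k:
        warnings.warn(f"a class has fewer members ({counts.min()}) than folds ({k}); "
                      "stratification is best-effort")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


def train(model: ADMVNet, dataset: VolumeDataset, cfg: TrainConfig) -> list[dict]:
    """SGD with momentum and cosine-annealed learning rate; returns the
    per-epoch log.  A non-finite loss aborts the run and restores the last
    completed epoch's weights."""
    rng = np.random.default_rng(cfg.seed)
    opt = optim.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay)
    history: list[dict] = []
    last_good = model.state_dict()
    n = len(dataset)
    for epoch in range(cfg.epochs):
        model.train()
        opt.lr = optim.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            gm, wm, pet, prof, y = dataset.batch(idx)
            out = model(gm, wm, pet, roi_profile=prof)
            loss = core.cross_entropy(out["y_hat"], y)
            if cfg.aux_loss_weight > 0:
                # deep supervision: each logit branch sees the labels
                # directly, so the ROI head keeps training even once the
                # fused loss is small
                aux = core.cross_entropy(out["y_c"], y)
                if "y_cr" in out:
                    aux = aux + core.cross_entropy(out["y_cr"], y)
                loss = loss + cfg.aux_loss_weight * aux
            if not np.isfinite(loss.data):
                model.load_state_dict(last_good)
                logger.error("non-finite loss at epoch %d; restoring last-good "
                             "weights and aborting", epoch)
                history.append({"epoch": epoch, "lr": opt.lr,
                                "loss": float("nan"), "acc": float("nan"),
                                "aborted": True})
                return history
            opt.zero_grad()
            loss.backward()
            if cfg.clip_norm is not None:
                total = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in model.parameters() if p.grad is not None))
                if total > cfg.clip_norm:
                    scale = cfg.clip_norm / (total + 1e-12)
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            losses.append(float(loss.data))
            correct += int((out["y_hat"].data.argmax(axis=1) == y).sum())
        last_good = model.state_dict()
        history.append({"epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses)), "acc": correct / n,
                        "aborted": False})
        logger.info("epoch %d: lr=%.5f loss=%.4f acc=%.3f",
                    epoch, opt.lr, history[-1]["loss"], history[-1]["acc"])
    return history


def evaluate(model: ADMVNet, dataset: VolumeDataset, batch_size: int = 8) -> dict:
    """Forward the dataset in eval mode; returns labels, argmax predictions,
    positive-class scores and the mean ROI-importance vector."""
    model.eval()
    preds, scores, importances = [], [], []
    n = len(dataset)
    with core.no_grad():
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            gm, wm, pet, prof, _ = dataset.batch(idx)
            out = model(gm, wm, pet, roi_profile=prof)
            logits = out["y_hat"].data
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            preds.append(logits.argmax(axis=1))
            scores.append(p[:, 1])
            if out["importance"] is not None:
                importances.append(out["importance"].data)
    return {
        "labels": dataset.labels.copy(),
        "predictions": np.concatenate(preds),
        "scores": np.concatenate(scores),
        "importance": (np.concatenate(importances).mean(axis=0)
                       if importances else None),
    }


# ---------------------------------------------------------------------------
# estimator / results
# ---------------------------------------------------------------------------

class ADMVNetResults:
    """Fit results: trained network, training log, held-out metrics and the
    ROI-importance ranking."""

    def __init__(self, model: ADMVNet, history: list[dict],
                 metrics: MetricsReport | None, importance: np.ndarray | None,
                 train_config: TrainConfig):
        self.model = model
        self.history = history
        self.metrics = metrics
        self.importance = importance
        self.train_config = train_config

    @property
    def converged(self) -> bool:
        return bool(self.history) and not self.history[-1].get("aborted", False)

    def roi_report(self, region_names=None) -> pd.DataFrame:
        from .ripm import export_roi_report
        if self.importance is None:
            raise ValueError("model was fitted without the ROI branch")
        return export_roi_report(self.importance, region_names)

    def summary(self) -> str:
        lines = ["ADMV-Net fit results", "=" * 52]
        lines.append(f"epochs run          : {len(self.history)}")
        if self.history:
            lines.append(f"final training loss : {self.history[-1]['loss']:.4f}")
            lines.append(f"final training acc  : {self.history[-1]['acc']:.3f}")
        if self.metrics is not None:
            m = self.metrics
            auc = f"{m.auc:.3f}" if m.auc is not None else "n/a"
            lines.append("held-out evaluation :")
            lines.append(f"  ACC {m.acc:.3f}  SEN {m.sen:.3f}  SPEC {m.spec:.3f}"
                         f"  BAC {m.bac:.3f}  AUC {auc}")
            c = m.confusion
            lines.append(f"  confusion TP={c['TP']} FP={c['FP']} FN={c['FN']} TN={c['TN']}")
        if self.importance is not None:
            top = self.roi_report().head(5)
            regions = ", ".join(f"{int(r.region_id)}({r.weight:.4f})"
                                for r in top.itertuples())
            lines.append(f"top ROI weights     : {regions}")
        return "\n".join(lines)

    def plot_loss(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot([h["epoch"] for h in self.history],
                [h["loss"] for h in self.history], marker="o")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class ADMVNetClassifier:
    """Estimator over a `VolumeDataset` (statsmodels-style model object)."""

    def __init__(self, dataset: VolumeDataset,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 standardize: bool = True):
        if len(np.unique(dataset.labels)) < 2:
            raise ValueError("training data must contain both classes")
        self.dataset = dataset
        self.model_config = model_config or ModelConfig.reduced()
        self.train_config = train_config or TrainConfig.reduced()
        self.standardize = standardize

    @classmethod
    def from_samples(cls, samples, parcellation, **kwargs) -> "ADMVNetClassifier":
        return cls(VolumeDataset(samples, parcellation), **kwargs)

    def fit(self, eval_dataset: VolumeDataset | None = None) -> ADMVNetResults:
        if self.standardize:
            train_ds, stats = self.dataset.standardize()
        else:
            train_ds, stats = self.dataset, None
        model = ADMVNet(self.model_config)
        history = train(model, train_ds, self.train_config)
        target = eval_dataset if eval_dataset is not None else self.dataset
        if self.standardize:
            target, _ = target.standardize(stats)
        ev = evaluate(model, target, batch_size=self.train_config.batch_size)
        metrics = compute_metrics(ev["labels"], ev["predictions"], ev["scores"])
        importance = ev["importance"]
        return ADMVNetResults(model, history, metrics, importance, self.train_config)


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class CVResults:
    per_fold: list[MetricsReport]
    assignment: np.ndarray
    importance: np.ndarray | None = None
    histories: list[list[dict]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.per_fold])

    def aggregate(self) -> pd.DataFrame:
        df = self.frame()[["acc", "sen", "spec", "bac", "auc"]].astype(float)
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"{len(self.per_fold)}-fold cross-validation", "=" * 40]
        for name, row in agg.iterrows():
            lines.append(f"{name.upper():5s}: {100 * row['mean']:.2f} "
                         f"+/- {100 * row['sd']:.2f} %")
        return "\n".join(lines)


def cross_validate(model_cfg: ModelConfig, train_cfg: TrainConfig,
                   dataset: VolumeDataset, standardize: bool = True) -> CVResults:
    """Stratified k-fold protocol: a fresh network per fold, trained on the
    other folds and evaluated on the held-out one.  Intensity
    standardization statistics are estimated on each training split only."""
    assignment = kfold_split(dataset.subject_ids, dataset.labels,
                             k=train_cfg.folds, seed=train_cfg.seed)
    reports, importances, histories = [], [], []
    for fold in range(train_cfg.folds):
        test_idx = np.where(assignment == fold)[0]
        train_idx = np.where(assignment != fold)[0]
        train_ids = {dataset.subject_ids[i] for i in train_idx}
        test_ids = {dataset.subject_ids[i] for i in test_idx}
        if train_ids & test_ids:
            raise RuntimeError(f"subject leakage between folds: {train_ids & test_ids}")
        fold_model_cfg = replace(model_cfg, seed=model_cfg.seed + fold)
        fold_train_cfg = replace(train_cfg, seed=train_cfg.seed + fold)
        model = ADMVNet(fold_model_cfg)
        fold_train = dataset.subset(train_idx)
        fold_test = dataset.subset(test_idx)
        if standardize:
            fold_train, stats = fold_train.standardize()
            fold_test, _ = fold_test.standardize(stats)
        histories.append(train(model, fold_train, fold_train_cfg))
        ev = evaluate(model, fold_test, batch_size=train_cfg.batch_size)
        reports.append(compute_metrics(ev["labels"], ev["predictions"], ev["scores"]))
        if ev["importance"] is not None:
            importances.append(ev["importance"])
        logger.info("fold %d: %s", fold, reports[-1])
    imp = np.mean(importances, axis=0) if importances else None
    return CVResults(per_fold=reports, assignment=assignment,
                     importance=imp, histories=histories)


def t_sweep(model_cfg: ModelConfig, train_cfg: TrainConfig,
            dataset: VolumeDataset, t_grid=(1, 3, 5, 7, 9)) -> pd.DataFrame:
    """Cross-validated accuracy as a function of the ROI-iteration count t."""
    rows = []
    for t in t_grid:
        cfg_t = copy.deepcopy(model_cfg)
        cfg_t.ripm.t = int(t)
        cv = cross_validate(cfg_t, train_cfg, dataset)
        agg = cv.aggregate()
        rows.append({"t": int(t),
                     "acc_mean": float(agg.loc["acc", "mean"]),
                     "acc_sd": float(agg.loc["acc", "sd"]),
                     "auc_mean": float(agg.loc["auc", "mean"]),
                     "auc_sd": float(agg.loc["auc", "sd"])})
    return pd.DataFrame(rows)
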