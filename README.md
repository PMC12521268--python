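# admvnet

A multi-view multimodal 3D network for Alzheimer's-stage classification
from paired structural-MRI tissue maps (grey matter, white matter) and PET
volumes — rebuilt as a tested, CPU-only Python package with a synthetic
phantom generator, so every mechanism can be exercised and verified
without access-restricted neuroimaging data.

It is aimed at researchers who want to study, probe or extend this family
of multimodal fusion architectures: every component is a small, seeded,
independently tested module, and the planted-signal phantoms make claims
like "the model localises disease-affected regions" falsifiable.

## The model

Three weight-independent four-stage backbones (GM, WM, PET) combine a
standard convolution path with an explicit anisotropic-diffusion path
guided by semantic feature differences,

    Fhat_p = Σ_{pe∈δ_p} h(‖G_pe − G_p‖²) (F_pe − F_p),
    F ← λF + νFhat   (T iterations),

where δ_p is the 6-connected neighborhood, G a down/up-sampled semantic
guide and h a learnable nonnegative scalar map — edge-preserving smoothing
that sharpens ambiguous anatomical boundaries.  Three fusion views then
summarise the hierarchy:

* **F_g (global)** — per-modality multi-head attention with
  depthwise-convolutional position mixing, a parameter-free batchwise
  normalizer that removes each modality's linear predictability from the
  previous one, and window attention over the summed modalities;
* **F_m (local)** — stages 1–3 aligned to a common width and fused by a
  bidirectional pass of weighted fusion nodes,
  `F_out = Σ w_i U(F_i) / (Σ w_i + ε)` with learnable nonnegative w;
* **F_b (latent)** — channel-attention-gated descriptors combined by
  pairwise per-channel outer products, sum-pooled and L2-normalized.

The concatenated views feed a classifier producing trunk logits `y_c`; a
regional-interest module then iterates attention plus a gated-recurrent
update over a 90-element brain-region weight vector ω (grounded in
per-region intensity profiles over an AAL-style 90-region parcellation),
emits ROI logits `y_cr`, and fuses `ŷ = y_c + σ(α)·y_cr`.  softmax(ω) is
the reported per-region importance.  Everything runs on a compact numpy
reverse-mode autodiff core — no GPU, no deep-learning framework.

See `docs/methods.md` for assumptions, parameter meanings and the design
choices made where the architecture left freedom.

## Worked example

```python
import numpy as np
from admvnet import (ADMVNetClassifier, ModelConfig, SyntheticConfig,
                     TrainConfig, VolumeDataset, generate_dataset)

cfg = SyntheticConfig(n_per_class=45, seed=0)   # 24³ phantoms, 8 planted regions
samples, parc = generate_dataset(cfg)
data = VolumeDataset(samples, parc)
train_ds, test_ds = data.subset(np.arange(60)), data.subset(np.arange(60, 90))

clf = ADMVNetClassifier(train_ds, ModelConfig.reduced(seed=0),
                        TrainConfig.reduced(seed=0))
res = clf.fit(eval_dataset=test_ds)
print(res.summary())
```

prints (about two minutes on one CPU core):

```
ADMV-Net fit results
====================================================
epochs run          : 10
final training loss : 0.2051
final training acc  : 1.000
held-out evaluation :
  ACC 0.867  SEN 0.867  SPEC 0.867  BAC 0.867  AUC 0.911
  confusion TP=13 FP=2 FN=2 TN=13
top ROI weights     : 71(0.0113), 38(0.0113), 5(0.0113), 27(0.0113), 49(0.0113)
```

Reading: the network, trained on 30 subjects per class, classifies the 15
held-out subjects per class with 86.7% accuracy and 0.911 AUC, and the
five most important regions in the learned ROI ranking (71, 38, 5, 27, 49)
are all members of the planted set {5, 16, 27, 38, 49, 60, 71, 82} — the
regions into which
the generator injected atrophy/hypometabolism.  `res.roi_report()` returns
the full ranked table; `res.plot_loss()` the training curve.

`cross_validate` and `t_sweep` run the 10-fold protocol and the
ROI-iteration-count study; the `admvnet` command line (`synth`, `train`,
`cv`, `tsweep`, `roi-report`, `eval`) wraps the same functions and reads /
writes NIfTI volumes with a CSV manifest, so preprocessed real data can be
dropped in.

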