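"""NIfTI persistence for synthetic and real datasets.

Layout: one directory per subject (gm.nii.gz, wm.nii.gz, pet.nii.gz), a
shared parcellation.nii.gz and a manifest CSV (subject_id, label, paths).
Synthetic volumes are written with an identity affine; loaders validate
that all volumes of a subject share grid and affine (no silent resampling).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import MultimodalSample, ParcellationMap

MODALITY_FILES = ("gm.nii.gz", "wm.nii.gz", "pet.nii.gz")


def save_dataset(samples: list[MultimodalSample], parc: ParcellationMap,
                 out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int16), affine),
             out_dir / "parcellation.nii.gz")
    rows = []
    for s in samples:
        sub_dir = out_dir / s.subject_id
        sub_dir.mkdir(exist_ok=True)
        for fname, vol in zip(MODALITY_FILES, (s.gm, s.wm, s.pet)):
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), sub_dir / fname)
        rows.append({"subject_id": s.subject_id, "label": s.label,
                     "gm": str(sub_dir / MODALITY_FILES[0]),
                     "wm": str(sub_dir / MODALITY_FILES[1]),
                     "pet": str(sub_dir / MODALITY_FILES[2])})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_nifti_subject(paths: dict, parcellation_path, label: int = 0,
                       subject_id: str = "subject") -> MultimodalSample:
    """Load one subject's co-registered GM/WM/PET triplet.

    ``paths``: mapping with keys gm/wm/pet.  Grid or affine mismatches
    raise; nothing is resampled silently.
    """
    parc_img = nib.load(str(parcellation_path))
    parc = ParcellationMap(np.asarray(parc_img.dataobj).astype(np.int32))
    vols = {}
    for key in ("gm", "wm", "pet"):
        img = nib.load(str(paths[key]))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.shape != parc.shape:
            raise ValueError(f"{key} grid {data.shape} does not match "
                             f"parcellation grid {parc.shape}")
        if not np.allclose(img.affine, parc_img.affine, atol=1e-5):
            raise ValueError(f"{key} affine does not match the parcellation affine")
        vols[key] = data
    return MultimodalSample(vols["gm"], vols["wm"], vols["pet"],
                            int(label), subject_id, parc)


def load_manifest(manifest_path) -> tuple[list[MultimodalSample], ParcellationMap]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    parc_path = manifest_path.parent / "parcellation.nii.gz"
    samples = [
        load_nifti_subject({"gm": row.gm, "wm": row.wm, "pet": row.pet},
                           parc_path, label=int(row.label),
                           subject_id=str(row.subject_id))
        for row in df.itertuples()
    ]
    return samples, samples[0].parcellation
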