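"""File dialects: group-volume bundles (NIfTI) and table round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .evidence import EvidenceMap, GroupDataset, LBFMap, VolumeGrid

__all__ = [
    "save_volume",
    "load_volume",
    "write_group_dataset",
    "read_group_dataset",
    "save_map",
]


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             affine if affine is not None else np.eye(4)),
             str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_map(m: EvidenceMap | LBFMap, path, fill: float = 0.0,
             affine: np.ndarray | None = None) -> None:
    save_volume(path, m.grid.embed(m.values, fill=fill), affine)


def write_group_dataset(dataset: GroupDataset, out_dir) -> None:
    """Persist a group dataset: 4D contrast/baseline NIfTI, mask, design CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = dataset.affine if dataset.affine is not None else np.eye(4)
    n = len(dataset.subjects)
    vol4 = np.zeros(dataset.grid.dims + (n,), dtype=np.float32)
    for i in range(n):
        vol4[..., i][dataset.grid.mask] = dataset.contrast[i]
    save_volume(out / "contrast.nii.gz", vol4, affine)
    save_volume(out / "mask.nii.gz",
                dataset.grid.mask.astype(np.float32), affine)
    if dataset.baseline is not None:
        base4 = np.zeros_like(vol4)
        for i in range(n):
            base4[..., i][dataset.grid.mask] = dataset.baseline[i]
        save_volume(out / "baseline.nii.gz", base4, affine)
    design = dataset.design.copy()
    design.insert(0, "subject_id", dataset.subjects)
    design.to_csv(out / "design.csv", index=False)


def read_group_dataset(in_dir) -> GroupDataset:
    src = Path(in_dir)
    mask_vol, affine = load_volume(src / "mask.nii.gz")
    mask = mask_vol > 0.5
    grid = VolumeGrid(dims=mask.shape, mask=mask)
    vol4, _ = load_volume(src / "contrast.nii.gz")
    design = pd.read_csv(src / "design.csv")
    subjects = design.pop("subject_id").astype(str).tolist()
    contrast = np.stack([vol4[..., i][mask] for i in range(vol4.shape[-1])])
    baseline = None
    if (src / "baseline.nii.gz").exists():
        base4, _ = load_volume(src / "baseline.nii.gz")
        baseline = np.stack(
            [base4[..., i][mask] for i in range(base4.shape[-1])]
        )
    return GroupDataset(
        subjects=subjects, grid=grid, contrast=contrast,
        design=design, baseline=baseline, affine=affine,
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
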