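"""NIfTI persistence of paired studies.

Each study is stored as ``<id>_nac.nii.gz`` and ``<id>_asc.nii.gz`` (2D
slices as single-slice volumes; the affine encodes the in-plane pixel size
and the slice thickness) plus a JSON sidecar with the SUV metadata and
provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CenterDataset, CenterProfile, PairedStudy
from .preprocessing import GridSpec

__all__ = ["write_study", "read_study", "write_center_dataset", "read_center_dataset"]


def _affine(grid: GridSpec, slice_thickness_mm: float) -> np.ndarray:
    sy, sx = grid.spacing_mm
    return np.diag([sx, sy, slice_thickness_mm, 1.0])


def write_study(study: PairedStudy, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.grid, study.slice_thickness_mm)
    for role, img in (("nac", study.nac_image), ("asc", study.asc_image)):
        vol = np.asarray(img, dtype=np.float32)[:, :, None]
        nib.save(nib.Nifti1Image(vol, aff), out_dir / f"{study.study_id}_{role}.nii.gz")
    sidecar = {
        "study_id": study.study_id,
        "injected_activity_MBq": study.injected_activity_MBq,
        "body_weight_kg": study.body_weight_kg,
        "center_id": study.center_id,
        "seed": study.seed,
        "slice_thickness_mm": study.slice_thickness_mm,
        "spacing_mm": list(study.grid.spacing_mm),
    }
    (out_dir / f"{study.study_id}.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_study(out_dir, study_id: str) -> PairedStudy:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{study_id}.json").read_text())
    imgs = {}
    for role in ("nac", "asc"):
        vol = nib.load(out_dir / f"{study_id}_{role}.nii.gz")
        imgs[role] = np.asarray(vol.dataobj, dtype=np.float64)[:, :, 0]
    h, w = imgs["nac"].shape
    grid = GridSpec(spacing_mm=tuple(meta["spacing_mm"]), size=(h, w))
    return PairedStudy(
        study_id=meta["study_id"],
        nac_image=imgs["nac"],
        asc_image=imgs["asc"],
        injected_activity_MBq=meta["injected_activity_MBq"],
        body_weight_kg=meta["body_weight_kg"],
        grid=grid,
        slice_thickness_mm=meta["slice_thickness_mm"],
        center_id=meta["center_id"],
        seed=meta["seed"],
    )


def write_center_dataset(dataset: CenterDataset, out_dir) -> Path:
    out_dir = Path(out_dir) / dataset.profile.center_id
    for study in dataset.studies:
        write_study(study, out_dir)
    manifest = {
        "profile": dataset.profile.__dict__,
        "study_ids": [s.study_id for s in dataset.studies],
    }
    (out_dir / "center.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def read_center_dataset(center_dir) -> CenterDataset:
    center_dir = Path(center_dir)
    manifest = json.loads((center_dir / "center.json").read_text())
    profile = CenterProfile(**manifest["profile"])
    studies = [read_study(center_dir, sid) for sid in manifest["study_ids"]]
    return CenterDataset(profile=profile, studies=studies)
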