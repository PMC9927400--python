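"""Cohort persistence: NIfTI volumes/masks, clinical CSV, manifest JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import Volume3D
from .synth import CLINICAL_COLUMNS, ClinicalRecord, LesionCase


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # axis order (z, y, x) -> diag encodes per-axis spacing
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: Volume3D, path: Path, as_mask: bool = False) -> None:
    data = vol.intensities.astype(np.uint8 if as_mask else np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing))
    nib.save(img, str(path))


def read_volume(path: Path) -> Volume3D:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"failed to parse NIfTI file {path}: {exc}") from exc
    return Volume3D(data, spacing)


def write_cohort(cases: list[LesionCase], manifest: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for phase in ("pre", "post"):
            write_volume(getattr(case, f"{phase}_volume"), img_dir / f"{case.lesion_id}_{phase}.nii.gz")
            write_volume(
                getattr(case, f"{phase}_mask"),
                img_dir / f"{case.lesion_id}_{phase}_mask.nii.gz",
                as_mask=True,
            )
        row = {"lesion_id": case.lesion_id, "patient_id": case.patient_id}
        row.update(case.clinical.as_dict())
        row["label"] = case.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "clinical.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def read_cohort(in_dir: Path) -> list[LesionCase]:
    in_dir = Path(in_dir)
    clinical_path = in_dir / "clinical.csv"
    if not clinical_path.exists():
        raise IOError(f"missing clinical table {clinical_path}")
    table = pd.read_csv(clinical_path)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise IOError(f"clinical.csv missing columns {missing}")
    cases = []
    img_dir = in_dir / "images"
    for _, row in table.iterrows():
        lid = row["lesion_id"]
        record = ClinicalRecord(**{k: row[k] for k in CLINICAL_COLUMNS})
        cases.append(
            LesionCase(
                lesion_id=lid,
                patient_id=row["patient_id"],
                pre_volume=read_volume(img_dir / f"{lid}_pre.nii.gz"),
                pre_mask=read_volume(img_dir / f"{lid}_pre_mask.nii.gz"),
                post_volume=read_volume(img_dir / f"{lid}_post.nii.gz"),
                post_mask=read_volume(img_dir / f"{lid}_post_mask.nii.gz"),
                clinical=record,
                label=row["label"],
            )
        )
    return cases
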