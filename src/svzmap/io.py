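"""File formats and run configuration.

Volumes are NIfTI-1 (gzipped) with the template affine; subject tables are
CSV with header ``subject_id,subtype,mask_path``; configurations are YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import SUBTYPES, SubjectRecord, TemplateSpace
from .synthetic import CohortConfig

_AFFINE_ATOL = 1e-4


def save_nifti(path, array: np.ndarray, affine: np.ndarray) -> None:
    """Write an array as NIfTI-1; booleans are stored as uint8."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype == np.int64:
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def save_template(template: TemplateSpace, out_dir) -> Path:
    """Write brain and ventricle masks (NIfTI) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(out_dir / "brain_mask.nii.gz", template.brain_mask, template.affine)
    save_nifti(
        out_dir / "ventricle_mask.nii.gz", template.ventricle_mask, template.affine
    )
    return out_dir


def load_template(template_dir) -> TemplateSpace:
    """Load a template space from ``brain_mask.nii.gz`` + ``ventricle_mask.nii.gz``.

    Works equally for a synthetic template written by :func:`save_template`
    and for a real template (e.g. MNI152 masks) arranged the same way.
    """
    template_dir = Path(template_dir)
    brain, affine = load_nifti(template_dir / "brain_mask.nii.gz")
    vent, affine_v = load_nifti(template_dir / "ventricle_mask.nii.gz")
    if not np.allclose(affine, affine_v, atol=_AFFINE_ATOL):
        raise ValueError(
            f"brain and ventricle masks in {template_dir} have different affines"
        )
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return TemplateSpace(
        shape=brain.shape,
        spacing=spacing,
        affine=affine,
        brain_mask=brain > 0,
        ventricle_mask=vent > 0,
    )


def write_subjects(
    records: list[SubjectRecord], template: TemplateSpace, out_dir
) -> Path:
    """Write per-subject masks and the subject table CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    masks_dir = out_dir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        mask_path = masks_dir / f"{r.subject_id}.nii.gz"
        save_nifti(mask_path, r.ce_mask, template.affine)
        rows.append(
            {
                "subject_id": r.subject_id,
                "subtype": r.subtype,
                "mask_path": str(mask_path.relative_to(out_dir)),
            }
        )
    table_path = out_dir / "subjects.csv"
    pd.DataFrame(rows, columns=["subject_id", "subtype", "mask_path"]).to_csv(
        table_path, index=False
    )
    return table_path


def read_subjects(table_path, template: TemplateSpace) -> list[SubjectRecord]:
    """Load and validate subjects from a CSV table.

    Relative mask paths are resolved against the table's directory.
    Subtype labels are matched case-insensitively; masks are binarized at
    > 0 and checked against the template grid and affine (element-wise
    tolerance 1e-4).  Loaded masks are treated as raw (unfilled).
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path)
    required = ["subject_id", "subtype", "mask_path"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{table_path}: expected header {','.join(required)}, got {','.join(df.columns)}"
        )
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        subtype = str(row.subtype).strip().lower()
        if subtype not in SUBTYPES:
            raise ValueError(
                f"{table_path} row {row_no}: unrecognized subtype {row.subtype!r} "
                f"(expected one of {', '.join(SUBTYPES)})"
            )
        mask_path = Path(row.mask_path)
        if not mask_path.is_absolute():
            mask_path = table_path.parent / mask_path
        data, affine = load_nifti(mask_path)
        if data.shape != template.shape:
            raise ValueError(
                f"{mask_path}: mask shape {data.shape} != template shape {template.shape}"
            )
        if not np.allclose(affine, template.affine, atol=_AFFINE_ATOL):
            raise ValueError(
                f"{mask_path}: affine differs from the template affine by more "
                f"than {_AFFINE_ATOL}"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                subtype=subtype,
                ce_mask=data > 0,
                filled=False,
            )
        )
    return records


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    ``template_dir``/``subject_table`` may be None, in which case the
    pipeline generates the default synthetic template and cohort (seeded by
    ``seed``).  All analysis parameters carry their conventional defaults:
    10 mm periventricular band, 15 mm centroid spheres, 0.05 voxel- and
    cluster-level alphas, 1000 permutations.
    """

    out_dir: str = "svzmap_out"
    template_dir: str | None = None
    subject_table: str | None = None
    cohort: CohortConfig | None = None
    band_mm: float = 10.0
    sphere_radius_mm: float = 15.0
    voxel_alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    welch: bool = False
    weighted_mass: bool = True

    def validate(self) -> None:
        if self.band_mm < 0:
            raise ValueError("band_mm must be >= 0")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be positive")
        for name in ("voxel_alpha", "cluster_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.cohort is not None:
            self.cohort.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
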