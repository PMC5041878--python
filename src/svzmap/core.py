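"""Core domain types shared by every stage of the pipeline.

The analysis operates on per-subject binary contrast-enhancing (CE) tumor
masks that have already been registered to a common template space (for real
data, typically MNI152 1 mm^3).  The template space carries the voxel grid,
the voxel-to-world affine, a brain mask and a lateral-ventricle mask; all
distances and radii throughout the package are expressed in world
millimetres so that anisotropic voxel spacing is handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine

#: Transcriptomic glioblastoma subtype labels accepted throughout the
#: package, in canonical order.  ``gcimp`` is the G-CIMP (CpG island
#: methylator phenotype) group; ``unknown`` marks subjects without a
#: subtype call and is excluded from all statistical contrasts.
SUBTYPES: tuple[str, ...] = (
    "proneural",
    "neural",
    "classical",
    "mesenchymal",
    "gcimp",
    "unknown",
)


def _as_bool_mask(arr, name: str, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.asarray(arr)
    if out.shape != tuple(shape):
        raise ValueError(
            f"{name} has shape {out.shape}, expected template shape {tuple(shape)}"
        )
    return out.astype(bool, copy=False)


@dataclass(frozen=True)
class TemplateSpace:
    """A shared volumetric coordinate frame with brain and ventricle masks.

    Parameters
    ----------
    shape
        Grid dimensions in voxels, ``(nx, ny, nz)``.
    spacing
        Voxel edge lengths in mm, all strictly positive.
    affine
        4x4 voxel-index -> world-mm map (NIfTI convention, invertible).
    brain_mask, ventricle_mask
        Nonempty boolean arrays on the grid; every ventricle voxel must also
        be a brain voxel.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular (not invertible)")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(
            self, "brain_mask", _as_bool_mask(self.brain_mask, "brain_mask", shape)
        )
        object.__setattr__(
            self,
            "ventricle_mask",
            _as_bool_mask(self.ventricle_mask, "ventricle_mask", shape),
        )
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")
        if not self.ventricle_mask.any():
            raise ValueError("ventricle_mask is empty")
        if (self.ventricle_mask & ~self.brain_mask).any():
            raise ValueError(
                "invariant violated: every ventricle voxel must lie inside the brain mask"
            )

    # -- coordinate helpers -------------------------------------------------

    def voxel_to_world(self, indices) -> np.ndarray:
        """World-mm coordinates of voxel centers for (..., 3) index arrays."""
        return apply_affine(self.affine, np.asarray(indices, dtype=float))

    def world_to_voxel(self, points) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points."""
        inv = np.linalg.inv(self.affine)
        return apply_affine(inv, np.asarray(points, dtype=float))

    def world_x(self) -> np.ndarray:
        """World x-coordinate of every voxel center, as a 3D array."""
        ii = np.arange(self.shape[0], dtype=float)
        jj = np.arange(self.shape[1], dtype=float)
        kk = np.arange(self.shape[2], dtype=float)
        grid = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), axis=-1)
        return self.voxel_to_world(grid)[..., 0]

    @property
    def midplane_x(self) -> float:
        """World x of the interhemispheric midplane (mean over brain voxels)."""
        return float(self.world_x()[self.brain_mask].mean())


@dataclass
class SubjectRecord:
    """One subject: ID, subtype label and a binary CE mask in template space.

    ``filled`` records whether enclosed cavities in the CE mask have already
    been filled (the pipeline operates on filled masks throughout).
    """

    subject_id: str
    subtype: str
    ce_mask: np.ndarray
    filled: bool = False

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(
                f"subtype {self.subtype!r} not one of {', '.join(SUBTYPES)}"
            )
        self.ce_mask = np.asarray(self.ce_mask).astype(bool, copy=False)
        if not self.ce_mask.any():
            raise ValueError(f"subject {self.subject_id}: CE mask is empty")

    def validate_against(self, template: TemplateSpace) -> None:
        if self.ce_mask.shape != template.shape:
            raise ValueError(
                f"subject {self.subject_id}: mask shape {self.ce_mask.shape} "
                f"!= template shape {template.shape}"
            )
        if (self.ce_mask & ~template.brain_mask).any():
            raise ValueError(
                f"subject {self.subject_id}: CE mask extends outside the brain mask"
            )
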