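"""Tumor density maps and periventricular enrichment fractions.

A density map is the voxel-wise count of subjects whose (filled) CE mask
covers the voxel, divided by the number of subjects — the per-voxel
probability of tumor presence in the cohort.  A centroid density map is
the same construction applied to fixed-radius spheres (default 15 mm)
placed at each subject's tumor center of mass, which summarizes where
tumors are centered rather than where they extend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SubjectRecord, TemplateSpace
from .svz import DistanceMap, distance_transform
from .volume import centroid, centroid_sphere, fill_ce_volume


@dataclass(frozen=True)
class DensityMap:
    """Per-voxel overlap counts and probabilities for one subject group."""

    counts: np.ndarray
    probability: np.ndarray
    n_subjects: int
    group_label: str


def density_map(masks, group_label: str = "all") -> DensityMap:
    """Voxel-wise overlap count and count/N probability over binary masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("density_map needs at least one mask")
    shape = np.asarray(masks[0]).shape
    counts = np.zeros(shape, dtype=np.int64)
    for i, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError(
                f"mask {i} has shape {m.shape}, expected {tuple(shape)}"
            )
        counts += m.astype(bool)
    n = len(masks)
    return DensityMap(
        counts=counts,
        probability=counts / float(n),
        n_subjects=n,
        group_label=group_label,
    )


def centroid_density_map(
    records: list[SubjectRecord],
    template: TemplateSpace,
    radius_mm: float = 15.0,
    group_label: str = "centroid",
) -> DensityMap:
    """Density map of fixed-radius spheres at each subject's center of mass.

    Centroids are computed on filled masks; records not yet filled are
    filled on the fly.
    """
    spheres = []
    for r in records:
        mask = r.ce_mask if r.filled else fill_ce_volume(r.ce_mask)
        spheres.append(centroid_sphere(centroid(mask, template), radius_mm, template))
    return density_map(spheres, group_label=group_label)


def periventricular_fraction(
    dmap: DensityMap,
    template: TemplateSpace,
    band_mm: float = 10.0,
    weighted: bool = True,
    distance_map: DistanceMap | None = None,
) -> tuple[float, float]:
    """Share of tumor density mass inside the periventricular band.

    The band is the set of brain-mask voxels within ``band_mm`` of the
    nearest ventricle voxel (ventricle voxels themselves included, distance
    0).  Returns ``(mass_fraction, volume_fraction)`` where mass_fraction is
    the probability-weighted density mass inside the band over the total
    mass, and volume_fraction is the band's share of brain volume.  With
    ``weighted=False`` the mass fraction instead counts voxels with any
    tumor presence (probability > 0).

    Raises
    ------
    ValueError
        If the density map carries no mass (fraction undefined) or shapes
        disagree with the template.
    """
    if band_mm < 0:
        raise ValueError(f"band_mm must be >= 0, got {band_mm}")
    if dmap.probability.shape != template.shape:
        raise ValueError(
            f"density map shape {dmap.probability.shape} != template shape {template.shape}"
        )
    dist = (distance_map or distance_transform(template)).values
    band = template.brain_mask & (dist <= band_mm)
    if weighted:
        total = float(dmap.probability.sum())
        if total == 0:
            raise ValueError("density map has zero total mass; fraction undefined")
        mass_fraction = float(dmap.probability[band].sum()) / total
    else:
        present = dmap.probability > 0
        total = int(present.sum())
        if total == 0:
            raise ValueError("density map has zero total mass; fraction undefined")
        mass_fraction = float((present & band).sum()) / total
    volume_fraction = float(band.sum()) / float(template.brain_mask.sum())
    return mass_fraction, volume_fraction
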