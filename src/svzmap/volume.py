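"""Binary-mask geometry: cavity filling, centroids, centroid spheres.

Conventions: cavity filling treats the background as 6-connected (the
complementary-connectivity convention for 3D hole filling, so diagonal
"leaks" do not connect an enclosed cavity to the outside); centroids are
unweighted means of foreground voxel-center world coordinates; sphere
membership is decided by voxel centers (closed ball, no partial-volume
weighting).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import TemplateSpace


def fill_ce_volume(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed cavities of a binary mask.

    A cavity is a 6-connected background component that does not touch the
    array boundary.  The result is a superset of the input and the operation
    is idempotent.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    mask = np.asarray(mask).astype(bool, copy=False)
    if not mask.any():
        raise ValueError("cannot fill an empty mask")
    # binary_fill_holes with the default structure uses 6-connected background
    return ndi.binary_fill_holes(mask)


def centroid(mask: np.ndarray, template: TemplateSpace) -> np.ndarray:
    """Center of mass of a binary mask, in world mm.

    The unweighted mean of the world coordinates of all foreground voxel
    centers; returned as a length-3 array ``(x, y, z)``.
    """
    mask = np.asarray(mask).astype(bool, copy=False)
    if not mask.any():
        raise ValueError("cannot compute the centroid of an empty mask")
    idx = np.argwhere(mask)
    return template.voxel_to_world(idx).mean(axis=0)


def centroid_sphere(
    center: np.ndarray, radius_mm: float, template: TemplateSpace
) -> np.ndarray:
    """Rasterize a closed ball of ``radius_mm`` around a world-mm point.

    Returns the mask of all voxels whose world-coordinate centers lie within
    ``radius_mm`` of ``center``, clipped to the grid.  The conventional
    radius for centroid density maps is 15 mm.

    Raises
    ------
    ValueError
        If ``radius_mm`` is not positive, or the sphere lies entirely
        outside the grid.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    center = np.asarray(center, dtype=float)
    c_vox = template.world_to_voxel(center)
    # conservative per-axis half-width of the bounding box, in voxels
    half = radius_mm / np.asarray(template.spacing) + 1.0
    lo = np.maximum(np.floor(c_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + half).astype(int) + 1, template.shape)
    if (lo >= hi).any():
        raise ValueError(
            f"sphere at {center} with radius {radius_mm} mm lies entirely "
            f"outside the template grid {template.shape}"
        )
    sub = np.stack(
        np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        ),
        axis=-1,
    )
    world = template.voxel_to_world(sub)
    inside = ((world - center) ** 2).sum(axis=-1) <= radius_mm**2
    out = np.zeros(template.shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return out
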