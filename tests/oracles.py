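"""Brute-force reference computations shared by the test suite.

These deliberately recompute quantities by direct per-voxel scans or exact
enumeration, independently of the library's vectorized implementations.
"""

import numpy as np


def brute_force_distance(mask, spacing):
    """Per-voxel min Euclidean distance (mm) to any True voxel, by full scan."""
    sp = np.asarray(spacing, dtype=float)
    ref = np.argwhere(mask) * sp
    all_idx = np.argwhere(np.ones(mask.shape, dtype=bool)) * sp
    d = np.sqrt(((all_idx[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min(1)
    return d.reshape(mask.shape)


def brute_force_band(template, band_mm):
    """Brain voxels within band_mm of the ventricles, by full distance scan."""
    d = brute_force_distance(template.ventricle_mask, template.spacing)
    return template.brain_mask & (d <= band_mm)
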