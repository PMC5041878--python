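"""Minimal visualization helpers (plain heatmap exports, not figure styling)."""

from __future__ import annotations

import numpy as np

from .density import DensityMap


def save_density_heatmap(dmap: DensityMap, path, axis: int = 2, index: int | None = None):
    """Save a mid-volume slice of a density map as a PNG heatmap.

    ``axis`` selects the slicing axis (default axial, k); ``index`` the
    slice (default: middle of the volume).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vol = dmap.probability
    if index is None:
        index = vol.shape[axis] // 2
    sl = np.take(vol, index, axis=axis).T
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(sl, origin="lower", cmap="hot", vmin=0, vmax=max(vol.max(), 1e-9))
    ax.set_title(f"{dmap.group_label} (n={dmap.n_subjects})")
    ax.axis("off")
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
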