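"""Subventricular-zone (SVZ) distance statistics.

The per-subject statistic is the mean, over all voxels of the subject's
filled CE volume, of the Euclidean distance (world mm) to the nearest
ventricle voxel.  Voxels inside the ventricle lumen are at distance 0 —
a tumor sitting in the lumen counts as being at the SVZ.  Group contrasts
use the two-sample Student's t-test (pooled variance; Welch available via
a flag), reported two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .core import SUBTYPES, SubjectRecord, TemplateSpace


def euclidean_distance_mm(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Exact Euclidean distance (mm) from every voxel center to the nearest
    True voxel of ``mask``, honouring anisotropic spacing; 0 on the mask."""
    mask = np.asarray(mask).astype(bool, copy=False)
    if not mask.any():
        raise ValueError("reference mask is empty")
    return ndi.distance_transform_edt(~mask, sampling=spacing)


@dataclass(frozen=True)
class DistanceMap:
    """Distance-to-ventricle field for one template (values in mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]


def distance_transform(template: TemplateSpace) -> DistanceMap:
    """Distance of every voxel center to the nearest ventricle voxel.

    For voxel centers outside the ventricle mask this equals the distance
    to the ventricular border voxels, so no explicit surface extraction is
    needed; ventricle voxels themselves get 0.
    """
    values = euclidean_distance_mm(template.ventricle_mask, template.spacing)
    return DistanceMap(values=values, spacing=template.spacing)


def svz_distance(record: SubjectRecord, dmap: DistanceMap) -> float:
    """Mean distance-to-ventricle over the subject's filled CE voxels (mm)."""
    mask = record.ce_mask
    if not record.filled:
        from .volume import fill_ce_volume

        mask = fill_ce_volume(mask)
    if mask.shape != dmap.values.shape:
        raise ValueError(
            f"subject {record.subject_id}: mask shape {mask.shape} != "
            f"distance map shape {dmap.values.shape}"
        )
    if not mask.any():
        raise ValueError(f"subject {record.subject_id}: CE mask is empty")
    return float(dmap.values[mask].mean())


def svz_distance_table(
    records: list[SubjectRecord], dmap: DistanceMap
) -> pd.DataFrame:
    """Per-subject SVZ distances as a tidy table.

    Columns: ``subject_id``, ``subtype``, ``svz_distance_mm``, ``ce_voxels``.
    """
    rows = [
        {
            "subject_id": r.subject_id,
            "subtype": r.subtype,
            "svz_distance_mm": svz_distance(r, dmap),
            "ce_voxels": int(r.ce_mask.sum()),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["subject_id", "subtype", "svz_distance_mm", "ce_voxels"])


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample contrast of per-subject SVZ distances."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def compare_groups(
    table: pd.DataFrame,
    group_a,
    group_b,
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t-test on SVZ distances between subtype sets.

    ``group_a``/``group_b`` are iterables of subtype labels pooled into one
    sample each.  The default is Student's pooled-variance test; pass
    ``welch=True`` for unequal variances.

    Raises
    ------
    ValueError
        If either group has fewer than two subjects, or the pooled variance
        is zero (both samples constant and equal — the t-statistic is
        undefined).
    """
    group_a = {group_a} if isinstance(group_a, str) else set(group_a)
    group_b = {group_b} if isinstance(group_b, str) else set(group_b)
    for g in (*group_a, *group_b):
        if g not in SUBTYPES:
            raise ValueError(f"unknown subtype {g!r}")
    a = table.loc[table["subtype"].isin(group_a), "svz_distance_mm"].to_numpy(float)
    b = table.loc[table["subtype"].isin(group_b), "svz_distance_mm"].to_numpy(float)
    label_a = "+".join(sorted(group_a))
    label_b = "+".join(sorted(group_b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 subjects (got {label_a}: {len(a)}, "
            f"{label_b}: {len(b)})"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError(
            f"zero pooled variance: all SVZ distances identical within "
            f"{label_a} and {label_b}; t-statistic undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
    )


#: The contrasts reported by default: each near-SVZ subtype against each
#: far subtype, plus the combined near-vs-far contrast.
DEFAULT_CONTRASTS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("proneural",), ("classical",)),
    (("proneural",), ("mesenchymal",)),
    (("neural",), ("classical",)),
    (("neural",), ("mesenchymal",)),
    (("proneural", "neural"), ("classical", "mesenchymal")),
)


def default_comparisons(
    table: pd.DataFrame, welch: bool = False
) -> list[GroupComparison]:
    """Run the standard near-vs-far SVZ contrasts, skipping any contrast
    for which a group has fewer than two subjects."""
    out: list[GroupComparison] = []
    counts = table["subtype"].value_counts()
    for ga, gb in DEFAULT_CONTRASTS:
        na = int(sum(counts.get(g, 0) for g in ga))
        nb = int(sum(counts.get(g, 0) for g in gb))
        if na < 2 or nb < 2:
            continue
        out.append(compare_groups(table, ga, gb, welch=welch))
    return out
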