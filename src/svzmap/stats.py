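"""Voxel-wise subtype association tests with cluster-level correction.

At every brain voxel, tumor presence (filled CE mask covers the voxel) is
cross-tabulated as subtype-of-interest vs all other labelled subtypes and
tested with a two-tailed Fisher's exact test.  Contiguous suprathreshold
regions (26-connectivity) are then screened by a max-cluster-size
permutation null: subtype labels are shuffled across subjects, the full
voxel-wise test is re-run for each shuffle, and a cluster is retained when
its size is improbably large under that null (family-wise control).

The two-tailed p-value uses the point-probability (minimum-likelihood)
convention: with all margins fixed, sum the hypergeometric probabilities
of every table at most as probable as the observed one (relative tie
tolerance 1e-9).  Because the voxel-wise p depends only on the per-group
presence counts, the whole map reduces to a lookup table indexed by
(count in subtype, count in rest), which is what makes exact permutation
re-testing affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps

from .core import SubjectRecord, TemplateSpace
from .volume import fill_ce_volume

_TIE_RTOL = 1e-9
_STRUCTURE_26 = ndi.generate_binary_structure(3, 3)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    a/b: subjects in the group of interest with/without tumor presence at
    the voxel; c/d: the same for all other subjects.  Returns the sum of
    hypergeometric point probabilities (margins fixed) of all tables no
    more probable than the observed one; p is clipped to (0, 1].
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("at least one margin must be positive")
    n_row = a + b  # group-of-interest size
    k_col = a + c  # subjects with tumor presence
    lo = max(0, n_row - (n_total - k_col))
    hi = min(n_row, k_col)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n_total, k_col, n_row)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


@lru_cache(maxsize=32)
def _pvalue_lookup(n_group: int, n_rest: int) -> np.ndarray:
    """Table of two-tailed p-values indexed [a, c] for fixed group sizes."""
    lut = np.ones((n_group + 1, n_rest + 1))
    for a in range(n_group + 1):
        for c in range(n_rest + 1):
            lut[a, c] = fisher_exact_2x2(a, n_group - a, c, n_rest - c)
    return lut


def _stack_presence(
    records: list[SubjectRecord], subtype: str, template: TemplateSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Filled-mask presence matrix over brain voxels + subtype indicator.

    Excludes ``unknown`` subjects from both margins.  Returns
    (presence: bool (n_subjects, n_brain_voxels), in_group: bool (n_subjects,)).
    """
    kept = [r for r in records if r.subtype != "unknown"]
    labels = {r.subtype for r in kept}
    if subtype not in labels:
        raise ValueError(f"subtype {subtype!r} absent from the cohort")
    if len(labels) < 2:
        raise ValueError(
            "need at least two labelled subtype groups (after excluding 'unknown')"
        )
    brain = template.brain_mask
    presence = np.empty((len(kept), int(brain.sum())), dtype=bool)
    for i, r in enumerate(kept):
        mask = r.ce_mask if r.filled else fill_ce_volume(r.ce_mask)
        presence[i] = mask[brain]
    in_group = np.array([r.subtype == subtype for r in kept])
    return presence, in_group


def _pmap_from_counts(
    a_counts: np.ndarray, totals: np.ndarray, lut: np.ndarray
) -> np.ndarray:
    """Vectorized p over brain voxels from per-group presence counts."""
    return lut[a_counts, totals - a_counts]


def voxelwise_subtype_test(
    records: list[SubjectRecord], subtype: str, template: TemplateSpace
) -> np.ndarray:
    """Dense map of two-tailed Fisher p-values for subtype vs rest.

    Every brain voxel with any tumor overlap is tested; voxels with no
    overlap, and voxels outside the brain mask, are assigned p = 1 so the
    output is shape-stable.
    """
    presence, in_group = _stack_presence(records, subtype, template)
    lut = _pvalue_lookup(int(in_group.sum()), int((~in_group).sum()))
    a_counts = presence[in_group].sum(axis=0)
    totals = presence.sum(axis=0)
    p_map = np.ones(template.shape)
    p_map[template.brain_mask] = _pmap_from_counts(a_counts, totals, lut)
    return p_map


@dataclass(frozen=True)
class ClusterResult:
    """Voxel-wise p-map with permutation-screened clusters for one subtype."""

    subtype: str
    p_map: np.ndarray
    voxel_alpha: float
    cluster_labels: np.ndarray
    cluster_sizes: list[int]
    cluster_p: list[float]
    retained: list[bool]
    n_permutations: int
    seed: int

    @property
    def retained_mask(self) -> np.ndarray:
        """Boolean mask of all voxels in retained clusters."""
        keep = np.flatnonzero(self.retained) + 1
        return np.isin(self.cluster_labels, keep)


def _max_cluster_size(supra_flat: np.ndarray, brain: np.ndarray, buf: np.ndarray) -> int:
    buf[...] = False
    buf[brain] = supra_flat
    labels, n = ndi.label(buf, structure=_STRUCTURE_26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_filter(
    p_map: np.ndarray,
    records: list[SubjectRecord],
    subtype: str,
    template: TemplateSpace,
    voxel_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Permutation screening of suprathreshold clusters.

    Thresholds ``p_map`` at ``voxel_alpha`` (strict), labels 26-connected
    components, and builds the null distribution of the maximum cluster
    size by shuffling the subtype indicator across (non-unknown) subjects
    ``n_permutations`` times, re-running the full voxel-wise exact test for
    each shuffle.  Cluster-level p uses the add-one estimator
    ``(1 + #{null max >= size}) / (n_permutations + 1)``; clusters with
    cluster_p <= cluster_alpha are retained.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    if p_map.shape != template.shape:
        raise ValueError(
            f"p_map shape {p_map.shape} != template shape {template.shape}"
        )
    supra = p_map < voxel_alpha
    cluster_labels, n_clusters = ndi.label(supra, structure=_STRUCTURE_26)
    sizes = (
        np.bincount(cluster_labels.ravel())[1:].astype(int).tolist()
        if n_clusters
        else []
    )

    presence, in_group = _stack_presence(records, subtype, template)
    lut = _pvalue_lookup(int(in_group.sum()), int((~in_group).sum()))
    totals = presence.sum(axis=0)
    pres_f = presence.astype(np.float32)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=np.int64)
    buf = np.zeros(template.shape, dtype=bool)
    brain = template.brain_mask
    chunk = 128
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm_ind = np.empty((m, len(in_group)), dtype=np.float32)
        for j in range(m):
            perm_ind[j] = rng.permutation(in_group).astype(np.float32)
        a_counts = np.rint(perm_ind @ pres_f).astype(np.intp)
        p_perm = lut[a_counts, totals[None, :] - a_counts]
        supra_perm = p_perm < voxel_alpha
        for j in range(m):
            null_max[done + j] = _max_cluster_size(supra_perm[j], brain, buf)
        done += m

    cluster_p = [
        float((1 + int((null_max >= s).sum())) / (n_permutations + 1)) for s in sizes
    ]
    retained = [p <= cluster_alpha for p in cluster_p]
    return ClusterResult(
        subtype=subtype,
        p_map=p_map,
        voxel_alpha=voxel_alpha,
        cluster_labels=cluster_labels,
        cluster_sizes=sizes,
        cluster_p=cluster_p,
        retained=retained,
        n_permutations=n_permutations,
        seed=seed,
    )


def cluster_table(result: ClusterResult) -> "pd.DataFrame":
    """Tidy per-cluster summary (id, size, cluster_p, retained, peak voxel)."""
    import pandas as pd

    rows = []
    for i, (size, p, keep) in enumerate(
        zip(result.cluster_sizes, result.cluster_p, result.retained), start=1
    ):
        in_cluster = result.cluster_labels == i
        # peak voxel: smallest voxel-wise p within the cluster
        flat = np.where(in_cluster, result.p_map, np.inf)
        peak = np.unravel_index(int(np.argmin(flat)), flat.shape)
        rows.append(
            {
                "cluster_id": i,
                "size_voxels": size,
                "cluster_p": p,
                "retained": keep,
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "size_voxels",
            "cluster_p",
            "retained",
            "peak_i",
            "peak_j",
            "peak_k",
        ],
    )
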