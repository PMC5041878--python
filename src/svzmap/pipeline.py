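"""End-to-end driver: fill -> density maps -> enrichment -> cluster maps
-> SVZ distances -> group comparisons, with all artifacts on disk and a
machine-readable JSON summary.  Fully deterministic for a fixed seed."""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np

from . import __version__
from .core import SUBTYPES, SubjectRecord, TemplateSpace
from .density import centroid_density_map, density_map, periventricular_fraction
from .io import RunConfig, load_template, read_subjects, save_nifti, save_template
from .stats import cluster_filter, cluster_table, voxelwise_subtype_test
from .svz import default_comparisons, distance_transform, svz_distance_table
from .synthetic import default_cohort_config, default_template, make_cohort
from .volume import fill_ce_volume

logger = logging.getLogger("svzmap")


def derive_seed(base: int, name: str) -> int:
    """Named deterministic substream seed (stable across runs/platforms)."""
    return (int(base) * 2654435761 + zlib.crc32(name.encode())) % (2**31)


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def run_pipeline(
    config: RunConfig,
    template: TemplateSpace | None = None,
    records: list[SubjectRecord] | None = None,
) -> dict:
    """Execute every analysis stage and write artifacts under ``config.out_dir``.

    Inputs may be passed in memory; otherwise they are loaded from
    ``config.template_dir``/``config.subject_table``, and if neither is set
    the default synthetic template and cohort are generated from
    ``config.seed``.  Returns the JSON-serializable summary (also written
    to ``summary.json``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- inputs -------------------------------------------------------------
    if template is None:
        if config.template_dir:
            template = load_template(config.template_dir)
            logger.info("loaded template from %s", config.template_dir)
        else:
            template = default_template()
            logger.info("generated default synthetic template %s", template.shape)
    if records is None:
        if config.subject_table:
            records = read_subjects(config.subject_table, template)
            logger.info("loaded %d subjects from %s", len(records), config.subject_table)
        else:
            cohort_cfg = config.cohort or default_cohort_config(
                seed=derive_seed(config.seed, "cohort")
            )
            records = make_cohort(template, cohort_cfg)
            logger.info("generated synthetic cohort of %d subjects", len(records))
    save_template(template, out_dir / "template")

    # -- stage: fill --------------------------------------------------------
    filled = [
        r
        if r.filled
        else SubjectRecord(r.subject_id, r.subtype, fill_ce_volume(r.ce_mask), True)
        for r in records
    ]
    n_by_subtype = {
        s: sum(1 for r in filled if r.subtype == s)
        for s in SUBTYPES
        if any(r.subtype == s for r in filled)
    }
    logger.info("cohort composition: %s", n_by_subtype)

    dist = distance_transform(template)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)

    # -- stage: density maps ------------------------------------------------
    total = density_map([r.ce_mask for r in filled], group_label="all")
    save_nifti(maps_dir / "density_all.nii.gz", total.probability, template.affine)
    subtype_maps = {}
    for s, n in n_by_subtype.items():
        dm = density_map(
            [r.ce_mask for r in filled if r.subtype == s], group_label=s
        )
        subtype_maps[s] = dm
        save_nifti(maps_dir / f"density_{s}.nii.gz", dm.probability, template.affine)
    cmap = centroid_density_map(
        filled, template, radius_mm=config.sphere_radius_mm
    )
    save_nifti(maps_dir / "density_centroid.nii.gz", cmap.probability, template.affine)

    # -- stage: periventricular enrichment ----------------------------------
    fractions = {}
    for label, dm in {"all": total, "centroid": cmap, **subtype_maps}.items():
        mass, vol = periventricular_fraction(
            dm,
            template,
            band_mm=config.band_mm,
            weighted=config.weighted_mass,
            distance_map=dist,
        )
        fractions[label] = {
            "mass_fraction": _round6(mass),
            "volume_fraction": _round6(vol),
        }
        logger.info(
            "periventricular band (%g mm) — %s: mass %.1f%%, volume %.1f%%",
            config.band_mm,
            label,
            100 * mass,
            100 * vol,
        )

    # -- stage: per-subtype cluster maps ------------------------------------
    testable_labels = [s for s in n_by_subtype if s != "unknown"]
    clusters_summary = {}
    if len(testable_labels) >= 2:
        stats_dir = out_dir / "clusters"
        stats_dir.mkdir(exist_ok=True)
        for s in testable_labels:
            p_map = voxelwise_subtype_test(filled, s, template)
            result = cluster_filter(
                p_map,
                filled,
                s,
                template,
                voxel_alpha=config.voxel_alpha,
                cluster_alpha=config.cluster_alpha,
                n_permutations=config.n_permutations,
                seed=derive_seed(config.seed, f"perm:{s}"),
            )
            save_nifti(stats_dir / f"pmap_{s}.nii.gz", p_map, template.affine)
            save_nifti(
                stats_dir / f"clusters_{s}.nii.gz",
                result.cluster_labels.astype(np.int32),
                template.affine,
            )
            cluster_table(result).to_csv(
                stats_dir / f"clusters_{s}.csv", index=False
            )
            clusters_summary[s] = {
                "n_clusters": len(result.cluster_sizes),
                "n_retained": int(sum(result.retained)),
                "retained_voxels": int(result.retained_mask.sum()),
                "min_cluster_p": _round6(min(result.cluster_p))
                if result.cluster_p
                else None,
            }
            logger.info(
                "subtype %s: %d suprathreshold clusters, %d retained",
                s,
                clusters_summary[s]["n_clusters"],
                clusters_summary[s]["n_retained"],
            )
    else:
        logger.warning(
            "only one labelled subtype present; voxel-wise subtype tests skipped"
        )

    # -- stage: SVZ distances and contrasts ----------------------------------
    table = svz_distance_table(filled, dist)
    table.to_csv(out_dir / "svz_distances.csv", index=False)
    comparisons = default_comparisons(table, welch=config.welch)
    comparisons_summary = [
        {
            "group_a": c.group_a,
            "group_b": c.group_b,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "mean_a_mm": _round6(c.mean_a),
            "mean_b_mm": _round6(c.mean_b),
            "median_a_mm": _round6(c.median_a),
            "median_b_mm": _round6(c.median_b),
            "t_statistic": _round6(c.t_statistic),
            "degrees_of_freedom": _round6(c.degrees_of_freedom),
            "p_value": float(c.p_value),
        }
        for c in comparisons
    ]
    for c in comparisons_summary:
        logger.info(
            "SVZ distance %s (mean %.1f mm) vs %s (mean %.1f mm): p = %.4g",
            c["group_a"],
            c["mean_a_mm"],
            c["group_b"],
            c["mean_b_mm"],
            c["p_value"],
        )

    group_distances = {
        s: {
            "n": int(n),
            "mean_mm": _round6(sub["svz_distance_mm"].mean()),
            "median_mm": _round6(sub["svz_distance_mm"].median()),
        }
        for s, n in n_by_subtype.items()
        for sub in [table[table["subtype"] == s]]
    }

    summary = {
        "svzmap_version": __version__,
        "parameters": {
            "band_mm": config.band_mm,
            "sphere_radius_mm": config.sphere_radius_mm,
            "voxel_alpha": config.voxel_alpha,
            "cluster_alpha": config.cluster_alpha,
            "n_permutations": config.n_permutations,
            "seed": config.seed,
            "welch": config.welch,
            "weighted_mass": config.weighted_mass,
        },
        "template": {
            "shape": list(template.shape),
            "spacing_mm": list(template.spacing),
            "brain_voxels": int(template.brain_mask.sum()),
            "ventricle_voxels": int(template.ventricle_mask.sum()),
        },
        "n_subjects": len(filled),
        "n_by_subtype": n_by_subtype,
        "periventricular_fractions": fractions,
        "clusters": clusters_summary,
        "svz_distance_by_subtype": group_distances,
        "comparisons": comparisons_summary,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %s", out_dir / "summary.json")
    return summary
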