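"""Tumor density maps and periventricular enrichment.

Layers the cohort's filled CE masks into a per-voxel probability map, does
the same with 15-mm spheres at each tumor centroid, and asks what share of
total tumor density sits within 10 mm of the ventricles versus the share
of brain volume that band occupies.  Enrichment means the first number
exceeds the second.
"""

from svzmap import (
    centroid_density_map,
    default_cohort_config,
    default_template,
    density_map,
    make_cohort,
    periventricular_fraction,
)

template = default_template()
records = make_cohort(template, default_cohort_config(seed=0))

total = density_map([r.ce_mask for r in records], group_label="all")
mass, vol = periventricular_fraction(total, template, band_mm=10)
print(f"peak overlap probability: {total.probability.max():.2f}")
print(f"tumor density mass within 10 mm of the ventricles: {100 * mass:.1f}%")
print(f"band share of brain volume:                        {100 * vol:.1f}%")
print(f"enrichment ratio: {mass / vol:.2f}x")

cmap = centroid_density_map(records, template, radius_mm=15)
cmass, _ = periventricular_fraction(cmap, template, band_mm=10)
print(f"centroid-sphere density mass in the band:          {100 * cmass:.1f}%")

for subtype in ("proneural", "mesenchymal"):
    dm = density_map([r.ce_mask for r in records if r.subtype == subtype],
                     group_label=subtype)
    m, _ = periventricular_fraction(dm, template, band_mm=10)
    print(f"  {subtype:<12} band mass {100 * m:.1f}%  (near subtypes score higher)")
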