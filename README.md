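# svzmap

Spatial localization analysis of glioblastoma subtypes in a shared brain
template space.

Glioblastoma transcriptomic subtypes (proneural, neural, classical,
mesenchymal, plus G-CIMP) are suspected to arise from different cells of
origin, and one observable correlate is **where** the tumors sit — in
particular how close they are to the subventricular zone (SVZ), the
neurogenic niche lining the lateral ventricles. Given per-subject binary
contrast-enhancing (CE) tumor masks already registered to a common template
(e.g. MNI152) and a subtype label per subject, `svzmap` computes:

- **Tumor density maps** — per-voxel overlap probability
  `P(v) = (1/N) Σ_i M_i(v)` over the cohort's filled CE masks `M_i`, plus
  *centroid density maps* built from 15-mm spheres placed at each tumor's
  center of mass;
- **Periventricular enrichment** — the share of total density mass lying
  within a 10-mm band of the ventricular surface, against the band's share
  of brain volume;
- **Subtype cluster maps** — at every voxel, a two-tailed Fisher's exact
  test on the 2×2 table (subtype vs rest × tumor presence vs absence),
  followed by cluster-level family-wise correction: suprathreshold
  (p < 0.05) voxels are grouped at 26-connectivity and a cluster is
  retained when its size beats a max-cluster-size permutation null
  (`cluster_p = (1 + #{perm max ≥ size}) / (n_perm + 1) ≤ 0.05`);
- **SVZ distance statistics** — per subject, the mean Euclidean distance
  (world mm, exact distance transform honouring anisotropic spacing) from
  every filled CE voxel to the nearest ventricle voxel, compared between
  subtype groups with a two-sample Student's t-test (Welch optional).

A fully seeded synthetic-data generator (toy template with brain and
ventricle masks; cohorts of solid spherical tumors with subtype-dependent
distance-to-ventricle distributions and optional left-hemisphere bias)
makes the entire pipeline runnable and testable with no external data.

## Worked example

```sh
python examples/02_density_maps.py
```

prints, for the default 50-subject synthetic cohort (seed 0):

```
peak overlap probability: 0.08
tumor density mass within 10 mm of the ventricles: 26.6%
band share of brain volume:                        13.7%
enrichment ratio: 1.94x
centroid-sphere density mass in the band:          23.5%
  proneural    band mass 56.3%  (near subtypes score higher)
  mesenchymal  band mass 0.6%  (near subtypes score higher)
```

i.e. about a quarter of all tumor density mass concentrates in a
periventricular band occupying only ~14% of brain volume — an enrichment of
roughly 2× — and the effect is carried by the near subtypes. The group
contrast (`examples/04_svz_distance.py`) then shows proneural+neural tumors
(mean SVZ distance 9.8 mm) significantly closer to the ventricles than
classical+mesenchymal (25.1 mm; t = −9.29, p = 7.8e−12 on this synthetic
cohort).

The other examples cover cohort simulation (`01`), cluster mapping (`03`)
and the SVZ distance table (`04`). The same stages are available as shell
subcommands:

```sh
svzmap simulate --out-dir data/
svzmap run-all --seed 7 --out-dir results/
svzmap compare --table results/svz_distances.csv \
    --contrast proneural+neural:classical+mesenchymal
```

`run-all` writes density/p-value/cluster volumes as NIfTI, tables as CSV,
and a machine-readable `summary.json`; identical seeds give byte-identical
summaries.

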