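# Methods

## Setting and data model

All analysis happens in a single shared template space: a voxel grid with a
voxel-to-world affine, a brain mask, and a lateral-ventricle mask
(`TemplateSpace`). Subjects contribute a binary contrast-enhancing (CE)
tumor mask on that grid plus a subtype label in {proneural, neural,
classical, mesenchymal, gcimp, unknown}. Registration is assumed done
upstream; masks that do not match the template grid or affine (element-wise
tolerance 1e-4) are rejected at load time. Every distance and radius in the
package is in world millimetres, so anisotropic voxel spacing is handled
uniformly. Input affines are expected to be axis-aligned (scaling plus
translation), the normal situation for resampled template-space data; the
distance transform uses per-axis spacing and would not account for an
oblique rotation.

## Pipeline stages and conventions

**Cavity filling.** CE rims often enclose a non-enhancing core; analysis
uses filled masks throughout. A cavity is a 6-connected background
component not touching the array boundary (the standard complementary
connectivity to 26-connected foreground, so diagonal "leaks" cannot drain a
cavity). Filling is monotone and idempotent. The connectivity convention is
a package choice; nothing downstream is sensitive to it for blob-like
masks.

**Centroids and centroid spheres.** The centroid is the unweighted mean of
foreground voxel-center world coordinates of the *filled* mask (no
intensity weighting — inputs are binary). Centroid density maps place a
closed ball (default radius 15 mm, voxel-center membership, clipped to the
grid) at each centroid.

**Density maps.** Counts are voxel-wise sums of binary masks; probability
is counts/N. Counts are additive across disjoint subject groups, which the
tests exploit as an invariant.

**Periventricular enrichment.** The band is the set of brain voxels whose
distance to the nearest ventricle voxel is ≤ 10 mm; ventricle voxels
themselves (distance 0) are included, since a band "within 10 mm of the
ventricular volume" naturally contains its boundary, and tumors reaching
the lumen should count as periventricular. The mass fraction is the
probability-weighted sum over the band divided by the total (a
voxel-presence variant is available via `weighted=False`); the volume
fraction is band voxels over brain voxels, lumen included. Whether the
denominator of a published band-volume share includes the lumen is a
genuine ambiguity; including it changes the fraction by well under a
percentage point at 10 mm.

**Voxel-wise exact tests.** At each voxel the 2×2 table is (subtype S vs
all other labelled subtypes) × (filled mask covers voxel or not);
`unknown` subjects are excluded from both margins. The two-tailed p-value
follows the point-probability (minimum-likelihood) convention: with margins
fixed, sum hypergeometric probabilities of every table no more probable
than the observed one, using a relative tie tolerance of 1e-9 (ties at
machine precision are common for symmetric margins). p depends only on the
pair (presence count in S, presence count in rest), so the whole map is a
lookup-table evaluation; the table is computed once per pair of group
sizes. Voxels with zero total overlap, and voxels outside the brain mask,
get p = 1, keeping p-maps dense and shape-stable.

**Cluster-level correction.** Suprathreshold voxels (p < voxel_alpha,
default 0.05, strict) are grouped at 26-connectivity. The null is the
distribution of the *maximum* suprathreshold cluster size under random
reassignment of the subtype indicator across subjects; each permutation
re-runs the full voxel-wise test via the lookup table (no approximation).
Cluster p-values use the add-one estimator
(1 + #{perm max ≥ observed size}) / (n_permutations + 1), so they are never
below 1/(n_permutations+1); clusters with cluster_p ≤ cluster_alpha
(default 0.05) are retained. This is the standard family-wise max-statistic
permutation procedure; a published description of keeping clusters with a
">5% probability of occurring by chance" is interpreted as the conventional
<5% criterion. Permutations are seeded and chunked deterministically.

**SVZ distance.** The distance field is the exact Euclidean distance
transform of the ventricle mask (scipy's EDT with per-axis sampling), zero
on ventricle voxels. For voxel centers outside the mask this equals the
distance to the ventricular border voxels, so no surface extraction is
needed. Treating lumen voxels as distance 0 (rather than positive
distance-to-border from inside) is deliberate: a tumor inside the lumen is
at the SVZ, not beyond it. The per-subject statistic is the unweighted mean
over filled CE voxels; both means and medians are reported per group since
skewed distributions make the two diverge.

**Group comparisons.** Two-sample two-tailed Student's t-test with pooled
variance by default (Welch behind a flag). The default report covers the
four pairwise near-vs-far contrasts ({proneural, neural} × {classical,
mesenchymal}) and the combined proneural+neural vs classical+mesenchymal
contrast. Degenerate inputs (a group below two subjects, or zero pooled
variance) raise with a named cause rather than returning NaN.

## Synthetic data generator

The generator emulates the *structure* of a template-space lesion cohort,
not its appearance: an ellipsoidal brain (semi-axes 84% of the grid
half-extent) with two parallel ellipsoidal ventricle rods straddling the
midline; tumors are solid spheres (radius uniform in 6–14 mm) centered at a
brain voxel whose distance-to-ventricle matches a draw from the subtype's
Normal(mean, sd), truncated to achievable distances via rejection sampling
(cap 10,000 draws, then a descriptive error); the hemisphere is chosen by a
per-subtype left-probability. A single seeded stream per cohort, consumed
in canonical subtype order then subject order, makes cohorts bit-for-bit
reproducible.

Default study conditions: 50 subjects in proportions typical of a
subtyped glioblastoma cohort (proneural 11, neural 9, classical 12,
mesenchymal 13, gcimp 2, unknown 3); distance means 8/10/24/26 mm for
proneural/neural/classical/mesenchymal (gcimp 12, unknown 18) with sds
4–8 mm, larger for the far groups to mimic their more diffuse spread; left
bias 0.7 for proneural/neural, 0.5 otherwise. Published cohorts plot, but
do not tabulate, the subtype distance distributions, so these magnitudes
are illustrative: they encode the near/far ordering and plausible effect
sizes, chosen once. The default template is a 40³ grid at 3 mm — a
desk-scale stand-in for a 1-mm whole-brain template with ~18k brain voxels.

What the generator does **not** emulate: MR intensities or enhancement
appearance, irregular or multifocal tumor shapes, registration error,
mass effect, spatially varying tumor frequency beyond ventricle distance,
and any size–subtype correlation. Passing tests therefore demonstrate the
*statistical machinery* is correct and calibrated (exactness of the
transforms and tests, type-I error control, parameter recovery,
determinism), not that real glioblastoma cohorts will reproduce any
particular effect size.

## Numerical choices

- Fisher tie tolerance 1e-9 (relative); p clipped to (0, 1].
- Distance transform exactness is verified voxel-for-voxel (1e-9 mm)
  against brute-force scans on random anisotropic grids up to 32³.
- Permutation counts: 1000 by default in configurations; validation
  simulations use 200 permutations × 200 null cohorts (n = 40) on a 20³
  grid and 50 replicates for parameter recovery — sizes chosen to estimate
  the relevant rates with standard errors of a few percent while keeping
  the suite quick.
- Sphere membership uses voxel centers with a closed (≤) inequality;
  centroid spheres straddling the grid edge are clipped, erroring only
  when fully outside.
- JSON summaries round floats to 6 decimals except p-values (full
  precision) and sort keys, so identical seeds yield byte-identical files.

## Known limitations

- One-vs-rest contrasts per subtype only; no omnibus multi-group test and
  no FDR alternative to the family-wise cluster screen.
- Distances are Euclidean straight-line, not geodesic within white matter.
- The exact test treats subjects as exchangeable; no covariate adjustment
  (age, tumor volume) is available.
- The synthetic ventricle geometry is convex-ish and symmetric; real
  lateral ventricles are not, which mainly affects how often the truncated
  distance sampler needs to retry, not downstream statistics.
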