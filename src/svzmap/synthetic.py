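"""Synthetic template and tumor-cohort generation.

Real inputs to this pipeline are cohorts of binary contrast-enhancing (CE)
glioblastoma masks registered to a shared template (e.g. MNI152).  This
module fabricates a structurally analogous toy world so that every
downstream stage — density maps, voxel-wise exact tests, cluster
permutation correction, SVZ-distance statistics — can run and be tested
without any external data:

* a template with an ellipsoidal brain mask and two parallel ellipsoidal
  "lateral ventricle" rods straddling the midline;
* cohorts of solid (hole-free) spherical tumors whose center-to-ventricle
  distance is drawn per subtype from a truncated normal, emulating the
  qualitative finding that proneural/neural tumors sit near the
  ventricles while classical/mesenchymal tumors sit farther out and more
  diffusely, with an optional left-hemisphere placement bias.

Everything is deterministic given the configuration seed: one shared
seeded stream per cohort, consumed in subject order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import SUBTYPES, SubjectRecord, TemplateSpace
from .svz import euclidean_distance_mm


@dataclass(frozen=True)
class VentricleSpec:
    """Geometry of the two synthetic ventricle rods.

    All quantities are fractions of the grid's half-extent per axis, so the
    same spec scales across grid shapes and spacings.  Each rod is an
    ellipsoid elongated along y, its center offset laterally (along x) from
    the midline by ``lateral_offset_frac``.
    """

    lateral_offset_frac: float = 0.24
    semi_axes_frac: tuple[float, float, float] = (0.07, 0.45, 0.12)
    brain_semi_axes_frac: tuple[float, float, float] = (0.84, 0.84, 0.84)


def _ellipsoid_mask(template_world, center, semi_axes) -> np.ndarray:
    d = (template_world - np.asarray(center)) / np.asarray(semi_axes)
    return (d**2).sum(axis=-1) <= 1.0


def make_template(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    ventricle_spec: VentricleSpec | None = None,
) -> TemplateSpace:
    """Build a deterministic synthetic template space.

    The brain is an axis-aligned ellipsoid centered in the grid; the
    ventricles are two parallel ellipsoidal rods straddling the midline
    (two separate 26-connected components).  The affine is diagonal with
    the grid center at the world origin, so the interhemispheric midplane
    is the world plane x = 0.

    Raises
    ------
    ValueError
        If ``shape`` is below (16, 16, 16), spacing is not positive, or the
        requested ventricle geometry escapes the brain ellipsoid.
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if any(s < 16 for s in shape):
        raise ValueError(f"shape must be at least (16, 16, 16), got {shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    spec = ventricle_spec or VentricleSpec()

    sp = np.asarray(spacing)
    half_extent = sp * (np.asarray(shape) - 1) / 2.0
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = -half_extent

    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij"),
        axis=-1,
    )
    world = grid * sp - half_extent

    brain = _ellipsoid_mask(
        world, (0.0, 0.0, 0.0), np.asarray(spec.brain_semi_axes_frac) * half_extent
    )
    semi = np.asarray(spec.semi_axes_frac) * half_extent
    off = spec.lateral_offset_frac * half_extent[0]
    left = _ellipsoid_mask(world, (-off, 0.0, 0.0), semi)
    right = _ellipsoid_mask(world, (+off, 0.0, 0.0), semi)
    ventricle = left | right

    if not ventricle.any():
        raise ValueError("ventricle_spec produced an empty ventricle mask")
    if (ventricle & ~brain).any():
        raise ValueError(
            "invariant violated: ventricle_spec places ventricle voxels outside "
            "the brain mask (every ventricle voxel must lie inside the brain)"
        )
    return TemplateSpace(
        shape=shape,
        spacing=spacing,
        affine=affine,
        brain_mask=brain,
        ventricle_mask=ventricle,
    )


@dataclass
class CohortConfig:
    """Parameters of a synthetic subtype cohort.

    ``center_distance_mean``/``center_distance_sd`` (mm) give, per subtype,
    the normal distribution from which each tumor center's Euclidean
    distance to the nearest ventricle voxel is drawn (truncated to
    achievable distances by rejection sampling).  ``laterality_bias`` is the
    probability that a tumor center is placed in the left hemisphere
    (world x below the midplane).  Tumor radii are uniform in
    ``tumor_radius_range`` (mm).  The same config and seed always reproduce
    the identical cohort bit-for-bit.
    """

    n_per_subtype: dict[str, int]
    center_distance_mean: dict[str, float]
    center_distance_sd: dict[str, float]
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)
    laterality_bias: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    max_retries: int = 10_000

    def validate(self) -> None:
        for label, n in self.n_per_subtype.items():
            if label not in SUBTYPES:
                raise ValueError(f"unknown subtype label {label!r}")
            if n < 0:
                raise ValueError(f"n_per_subtype[{label!r}] must be >= 0, got {n}")
        if sum(self.n_per_subtype.values()) <= 0:
            raise ValueError("total cohort size must be positive")
        rmin, rmax = self.tumor_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(
                f"tumor_radius_range must satisfy 0 < min <= max, got {self.tumor_radius_range}"
            )
        for label in self.n_per_subtype:
            if self.n_per_subtype[label] == 0:
                continue
            if label not in self.center_distance_mean:
                raise ValueError(f"missing center_distance_mean for {label!r}")
            if self.center_distance_sd.get(label, 0.0) < 0:
                raise ValueError(f"center_distance_sd[{label!r}] must be >= 0")
            bias = self.laterality_bias.get(label, 0.5)
            if not 0.0 <= bias <= 1.0:
                raise ValueError(f"laterality_bias[{label!r}] must be in [0, 1]")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tumor_radius_range"] = list(self.tumor_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["tumor_radius_range"] = tuple(d.get("tumor_radius_range", (6.0, 14.0)))
        return cls(**d)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The package's default synthetic cohort.

    Fifty subjects with subtype proportions mirroring a typical
    transcriptomically-classified glioblastoma cohort, proneural/neural
    centers near the ventricles, classical/mesenchymal far and with larger
    spread, and a left-hemisphere bias for the proneural/neural groups.
    """
    return CohortConfig(
        n_per_subtype={
            "proneural": 11,
            "neural": 9,
            "classical": 12,
            "mesenchymal": 13,
            "gcimp": 2,
            "unknown": 3,
        },
        center_distance_mean={
            "proneural": 8.0,
            "neural": 10.0,
            "classical": 24.0,
            "mesenchymal": 26.0,
            "gcimp": 12.0,
            "unknown": 18.0,
        },
        center_distance_sd={
            "proneural": 4.0,
            "neural": 4.0,
            "classical": 6.0,
            "mesenchymal": 7.0,
            "gcimp": 5.0,
            "unknown": 8.0,
        },
        tumor_radius_range=(6.0, 14.0),
        laterality_bias={"proneural": 0.7, "neural": 0.7},
        seed=seed,
    )


def default_template() -> TemplateSpace:
    """Desk-scale default template: 40^3 grid at 3 mm isotropic spacing."""
    return make_template(shape=(40, 40, 40), spacing=(3.0, 3.0, 3.0))


class _TemplateSampler:
    """Precomputed per-template arrays used by tumor placement."""

    def __init__(self, template: TemplateSpace):
        self.template = template
        self.brain_idx = np.argwhere(template.brain_mask)
        world = template.voxel_to_world(self.brain_idx)
        self.world = world
        dmap = euclidean_distance_mm(template.ventricle_mask, template.spacing)
        self.dist = dmap[template.brain_mask]
        self.left = world[:, 0] < template.midplane_x
        self.max_dist = float(self.dist.max())
        # half the voxel diagonal: the natural distance resolution of the grid
        self.tol = 0.5 * float(np.linalg.norm(template.spacing))


def sample_tumor(
    template: TemplateSpace,
    subtype: str,
    config: CohortConfig,
    rng: np.random.Generator,
    _sampler: _TemplateSampler | None = None,
) -> np.ndarray:
    """Draw one solid spherical tumor mask for ``subtype``.

    The tumor center is a brain voxel whose distance to the nearest
    ventricle voxel matches a draw from the subtype's truncated normal
    (within half a voxel diagonal); the hemisphere is chosen by the
    subtype's laterality bias; the radius is uniform in the configured
    range.  The sphere is intersected with the brain mask, which keeps it
    hole-free (intersection of convex shapes).

    Raises
    ------
    RuntimeError
        If no achievable center is found within ``config.max_retries``
        draws; the message reports the requested distribution and the
        achievable distance range.
    """
    config.validate()
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    s = _sampler or _TemplateSampler(template)
    mean = config.center_distance_mean[subtype]
    sd = config.center_distance_sd.get(subtype, 0.0)
    bias = config.laterality_bias.get(subtype, 0.5)

    want_left = rng.random() < bias
    hemi = s.left if want_left else ~s.left
    radius = rng.uniform(*config.tumor_radius_range)

    chosen = -1
    for _ in range(config.max_retries):
        target = rng.normal(mean, sd) if sd > 0 else mean
        if target < -s.tol or target > s.max_dist + s.tol:
            continue  # truncation: outside achievable distances
        cand = np.flatnonzero(hemi & (np.abs(s.dist - target) <= s.tol))
        if cand.size:
            chosen = int(cand[rng.integers(cand.size)])
            break
    if chosen < 0:
        raise RuntimeError(
            f"no achievable tumor center for subtype {subtype!r} after "
            f"{config.max_retries} draws: requested distance ~N({mean}, {sd}^2) mm, "
            f"achievable range [0, {s.max_dist:.1f}] mm"
        )

    from .volume import centroid_sphere  # local import avoids a cycle at module load

    center_world = s.world[chosen]
    mask = centroid_sphere(center_world, radius, template) & template.brain_mask
    return mask


def make_cohort(
    template: TemplateSpace, config: CohortConfig
) -> list[SubjectRecord]:
    """Generate the full synthetic cohort described by ``config``.

    Pure and fully reproducible: a single stream seeded by ``config.seed``
    is consumed in canonical subtype order, then subject order.  Generated
    masks are solid, so records are created with ``filled=True``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sampler = _TemplateSampler(template)
    records: list[SubjectRecord] = []
    for subtype in SUBTYPES:
        n = config.n_per_subtype.get(subtype, 0)
        for i in range(n):
            mask = sample_tumor(template, subtype, config, rng, _sampler=sampler)
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{subtype}-{i:03d}",
                    subtype=subtype,
                    ce_mask=mask,
                    filled=True,
                )
            )
    return records
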