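import numpy as np
import pytest

from svzmap import CohortConfig, TemplateSpace, make_cohort, make_template


@pytest.fixture(scope="session")
def small_template():
    """32-mm-scale synthetic template: 24^3 grid at 2 mm isotropic."""
    return make_template(shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def flat_template():
    """Hand-built template with identity affine and a single ventricle voxel."""
    shape = (12, 12, 12)
    brain = np.ones(shape, dtype=bool)
    vent = np.zeros(shape, dtype=bool)
    vent[5, 5, 5] = True
    return TemplateSpace(
        shape=shape,
        spacing=(1.0, 1.0, 1.0),
        affine=np.eye(4),
        brain_mask=brain,
        ventricle_mask=vent,
    )


def two_group_config(seed=0, n=5, near=6.0, far=20.0, sd=2.0):
    return CohortConfig(
        n_per_subtype={"proneural": n, "classical": n},
        center_distance_mean={"proneural": near, "classical": far},
        center_distance_sd={"proneural": sd, "classical": sd},
        tumor_radius_range=(5.0, 9.0),
        seed=seed,
    )


@pytest.fixture()
def small_cohort(small_template):
    return make_cohort(small_template, two_group_config(seed=11))
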