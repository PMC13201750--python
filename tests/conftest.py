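"""Shared fixtures: a coarse synthetic atlas/frame and a small cohort.

Unit tests run on a 0.5 mm atlas for speed; the acceptance tests build
their own finer atlases where resolution matters.
"""

import numpy as np
import pytest

from sntarget.atlas import LabelAtlas
from sntarget.geometry import extend_virtual
from sntarget.synthetic import AnatomyParams, CohortParams, make_atlas, make_frame, sample_cohort


@pytest.fixture(scope="session")
def anatomy() -> AnatomyParams:
    return AnatomyParams(voxel_size_mm=0.5)


@pytest.fixture(scope="session")
def atlas(anatomy) -> LabelAtlas:
    return make_atlas(anatomy)


@pytest.fixture(scope="session")
def frame(anatomy):
    return make_frame(anatomy)


@pytest.fixture(scope="session")
def small_cohort(atlas, frame):
    """60 leads with virtual extensions, plus their generating record."""
    leads, record = sample_cohort(atlas, CohortParams(n_leads=60, seed=42), frame)
    return [extend_virtual(lead) for lead in leads], record


def half_space_atlas(voxel_size: float = 0.25, extent: float = 6.0) -> LabelAtlas:
    """Cube atlas whose SNr_R region is the half-space z < 0.

    Voxel centers sit at odd multiples of half the voxel size, so the z = 0
    boundary falls exactly between voxel layers and the rasterized region
    is volume-exact.
    """
    n = int(round(2 * extent / voxel_size))
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -extent + voxel_size / 2
    zs = affine[2, 3] + voxel_size * np.arange(n)
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[:, :, zs < 0] = 3
    return LabelAtlas(labels, affine, {"SNr_R": 3})
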