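import numpy as np
import pytest

from gmsuvr import CohortConfig, compute_suvr_table, generate_cohort
from gmsuvr import ALL_VOXELS, GM_MASKED
from gmsuvr.volume import AtlasParcellation, Volume

SMALL_GRID = (32, 40, 24)


def small_config(**overrides) -> CohortConfig:
    """A fast cohort configuration for unit tests (small grid, small n)."""
    kwargs = dict(n_ad=12, n_nonad=10, grid_shape=SMALL_GRID, voxel_size_mm=3.0, seed=7)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def noiseless_config(**overrides) -> CohortConfig:
    """All randomness off except what the test turns back on."""
    kwargs = dict(
        noise_sd=0.0,
        burden_sd=0.0,
        region_jitter_sd=0.0,
        atrophy_sd=0.0,
        nonad_atrophy_factor=0.0,
        global_scale_range=(1.0, 1.0),
    )
    kwargs.update(overrides)
    return small_config(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The full 51 AD / 43 non-AD cohort under default study conditions."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_suvr_tables(default_cohort):
    subjects, atlas = default_cohort
    return (
        compute_suvr_table(subjects, atlas, mode=ALL_VOXELS),
        compute_suvr_table(subjects, atlas, mode=GM_MASKED),
    )


def two_region_atlas(shape=(6, 6, 4), target_voxels=None, voxel_mm=2.0):
    """A hand-built parcellation: one target region (label 1) + reference (2).

    ``target_voxels``/reference default to two disjoint 2x2x2 corners.
    """
    labels = np.zeros(shape, dtype=np.int32)
    labels[0:2, 0:2, 0:2] = 1
    labels[-2:, -2:, -2:] = 2
    affine = np.diag([voxel_mm] * 3 + [1.0])
    vol = Volume(labels, affine)
    return AtlasParcellation(
        labels=vol, name_map={1: "target", 2: "cerebellum"}, reference_label=2
    )
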