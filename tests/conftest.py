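import logging

import numpy as np
import pandas as pd
import pytest

from vrconnectome.io import VolumeGrid
from vrconnectome.regions import Parcellation
from vrconnectome.synthetic import (
    BundleSpec,
    SyntheticConfig,
    make_cohort,
    make_parcellation,
    make_phantom,
    small_config,
)

logging.getLogger("vrconnectome").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def toy_parcellation():
    """A 4-region toy parcellation (2 left + 2 right blocks)."""
    cfg = SyntheticConfig(seed=0, n_regions=4, voxel_size_mm=2.0,
                          hemisphere_gap_vox=8, n_per_group=2)
    return make_parcellation(cfg)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config(seed=101, n_per_group=5)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return make_cohort(small_cfg)


@pytest.fixture(scope="session")
def tube_phantom():
    """Three straight interhemispheric FA tubes with distinct peaks.

    Used by the tracker tests: tubes run along x through the hemisphere gap,
    the direction field is zero outside them, and the top peak anchors
    FAT_max at 0.53.
    """
    cfg = SyntheticConfig(
        seed=7, n_regions=12, n_per_group=2,
        voxel_size_mm=2.0, hemisphere_gap_vox=22, tube_radius_mm=4.0,
        bundles=(
            BundleSpec(1, 7, n_fibers=5, peak_fa=0.53, fa_jitter=0.02, bow_mm=0.0),
            BundleSpec(3, 9, n_fibers=5, peak_fa=0.45, fa_jitter=0.02, bow_mm=0.0),
            BundleSpec(5, 11, n_fibers=5, peak_fa=0.35, fa_jitter=0.02, bow_mm=0.0),
        ),
    )
    parc = make_parcellation(cfg)
    phantom = make_phantom(cfg, parc, cfg.bundles)
    return cfg, parc, phantom


@pytest.fixture()
def fa_gradient_volume():
    """A small FA volume with a linear ramp along x for interpolation checks."""
    data = np.zeros((6, 5, 5))
    for i in range(6):
        data[i] = 0.1 * i
    return VolumeGrid(data=data, affine=np.diag([2.0, 2.0, 2.0, 1.0]))


def make_toy_parcellation_df():
    return pd.DataFrame({
        "id": [1, 2, 3, 4],
        "name": ["L01", "L02", "R01", "R02"],
        "hemisphere": ["L", "L", "R", "R"],
    })
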