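import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from focal3d import LocalizationTable, PopulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_table(rng):
    """Two tight Gaussian blobs of 200 points, centroids 500 nm apart."""
    a = rng.normal([0.0, 0.0, 0.0], 20.0, size=(200, 3))
    b = rng.normal([500.0, 0.0, 0.0], 20.0, size=(200, 3))
    return LocalizationTable(np.vstack([a, b]))


@pytest.fixture(scope="session")
def small_sim():
    """A small clustered dataset with ground truth: 12 clusters of mean
    radius 60 nm in a 12 um^3 box at moderate noise."""
    spec = PopulationSpec(
        n_clusters=12,
        radius_mean=60.0,
        radius_sd=12.0,
        dyes_mean=20.0,
        locs_per_dye_mean=10.0,
        min_separation=310.0,
    )
    return simulate_dataset([spec], zeta=0.01, rng_seed=42)
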