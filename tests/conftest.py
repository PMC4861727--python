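import numpy as np
import pytest

from voxdc import synthio


@pytest.fixture(scope="session")
def small_acq():
    """Compact acquisition for fast unit tests (still >= 1000 voxels)."""
    return synthio.AcquisitionConfig(grid_shape=(12, 14, 12), n_volumes=60)


@pytest.fixture(scope="session")
def desk_cohort():
    """Desk-scale cohort config + derived truth, shared across tests."""
    acq = synthio.AcquisitionConfig(grid_shape=(18, 22, 18))
    cfg = synthio.CohortConfig(acquisition=acq, seed=7)
    return cfg, synthio.build_truth(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
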