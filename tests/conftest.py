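import numpy as np
import pytest

import tractmix as tm


@pytest.fixture(scope="session")
def cohort48():
    """Default-shaped synthetic cohort (48 tracts x 7 patients) with truth."""
    cfg = tm.CohortSimConfig(seed=7)
    zs, truth = tm.simulate_zscore_cohort(cfg)
    return cfg, zs, truth


@pytest.fixture(scope="session")
def fitted_model(cohort48):
    """One mixture fit shared by posterior-summary and reporting tests."""
    _, zs, _ = cohort48
    return tm.TractMixture(
        n_chains=2, n_iterations=2500, burn_in=500, random_state=11
    ).fit(zs)


@pytest.fixture()
def small_phantom():
    cfg = tm.VoxelPhantomConfig(shape=(16, 16, 16), n_tracts=4, seed=2)
    return cfg, tm.simulate_voxel_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
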