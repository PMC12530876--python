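import numpy as np
import pytest

import smaopt as sm


@pytest.fixture(scope="session")
def space():
    return sm.lj_acquisition_space()


@pytest.fixture(scope="session")
def smooth_cfg():
    """Pure sigmoidal landscape: no ruggedness, noise, or failures."""
    return sm.OracleConfig(master_seed=0).smooth_only()


@pytest.fixture(scope="session")
def small_dataset(space, smooth_cfg):
    """64 Sobol points on the smooth landscape, all valid."""
    pts = sm.make_sobol(space, 6)
    return sm.evaluate_samples(pts, smooth_cfg, name="smooth64")


@pytest.fixture(scope="session")
def small_conformers():
    return sm.make_conformer_fixture(n_conformers=8, seed=1)
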