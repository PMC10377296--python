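import numpy as np
import pytest

from gbmgrowth.trajectory import CellTrajectory, GrowthParameters


@pytest.fixture
def small_trajectory() -> CellTrajectory:
    """Five-step trajectory small enough for exhaustive oracles."""
    return CellTrajectory(m=[4, 3, 5, 2, 3], m_star=[2, 1, 3, 0, 2],
                          delta_voxels=[120, 90, 200, 60, 150])


@pytest.fixture
def small_params() -> GrowthParameters:
    return GrowthParameters(nu=60.0, nu_star=25.0, lam=0.08, lam_star=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
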