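import numpy as np
import pytest

import petquant as pq


@pytest.fixture(scope="session")
def schedule():
    return pq.make_standard_frame_schedule()


@pytest.fixture(scope="session")
def input_fn():
    """Default synthetic input function (SUV-scale, 120 min, 0.05-min grid)."""
    return pq.simulate_input()


@pytest.fixture(scope="session")
def ref_params():
    """Reference 2TCM parameter set with V_T = (0.3/0.15)(1 + 0.06/0.03) = 6."""
    return pq.TwoTcmParams(K1=0.3, k2=0.15, k3=0.06, k4=0.03, vB=0.03)


@pytest.fixture(scope="session")
def ref_tac(ref_params, input_fn, schedule):
    return pq.simulate_tac(ref_params, input_fn, schedule, pq.NoiseSpec(0.0, 0))


@pytest.fixture(scope="session")
def param_grid():
    """3 x 3 x 3 grid of (K1, k2, k3) with k4, vB fixed."""
    grid = []
    for K1 in (0.2, 0.3, 0.45):
        for k2 in (0.1, 0.15, 0.25):
            for k3 in (0.015, 0.05, 0.09):
                grid.append(pq.TwoTcmParams(K1, k2, k3, 0.03, 0.03))
    return grid
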