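import numpy as np
import pytest

from lvmar.models import LVParameters, SimulationGrid
from lvmar.smoothing import Dataset
from lvmar.synthetic_data import make_lv_benchmark, make_mar_benchmark


@pytest.fixture(scope="session")
def logistic_params():
    """Single-species logistic: a=1, b=-0.5, carrying capacity 2."""
    return LVParameters(np.array([1.0]), np.array([[-0.5]]))


@pytest.fixture(scope="session")
def lv_benchmark():
    return make_lv_benchmark(seed=7)


@pytest.fixture(scope="session")
def mar_benchmark():
    return make_mar_benchmark(seed=11)


@pytest.fixture()
def logistic_dataset(logistic_params):
    """Noise-free logistic curve sampled on a 30-point grid."""
    from lvmar.models import simulate_lv_ode
    grid = SimulationGrid.over_span(0.0, 8.0, 30)
    traj = simulate_lv_ode(logistic_params, [0.1], grid)
    return Dataset(times=traj.times, values=traj.values)
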