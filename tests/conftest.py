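import numpy as np
import pytest

from taskstates import ERP, standard_layout_64
from taskstates.synth import make_prototype_maps


@pytest.fixture(scope="session")
def layout64():
    return standard_layout_64()


@pytest.fixture(scope="session")
def mapset6(layout64):
    return make_prototype_maps(layout64, 6, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_erp(data, rate=500.0, layout=None, subject="S1", condition="neutral"):
    """Wrap a channels x samples array into an ERP on a matching layout."""
    data = np.asarray(data, dtype=float)
    if layout is None:
        layout = standard_layout_64()
    times = -200.0 + np.arange(data.shape[1]) * 1000.0 / rate
    return ERP(subject, condition, data, rate, times, layout,
               n_trials_averaged=1)


@pytest.fixture
def small_layout():
    """A 4-channel toy layout for brute-force oracles."""
    from taskstates import SensorLayout
    pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
    return SensorLayout(("a", "b", "c", "d"), pos)
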