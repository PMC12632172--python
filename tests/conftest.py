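import numpy as np
import pytest

from phasemap import (
    DesignSpace,
    VariableSpec,
    balance_counter,
    fit_surrogate,
    random_batch,
    run_virtual_sample,
)
from phasemap.systems import demo_system_2d, demo_system_3d, demo_system_4d


@pytest.fixture(scope="session")
def system2d():
    return demo_system_2d()


@pytest.fixture(scope="session")
def system3d():
    return demo_system_3d()


@pytest.fixture(scope="session")
def system4d():
    return demo_system_4d()


@pytest.fixture(scope="session")
def space1d():
    return DesignSpace((VariableSpec("KCl", 4.0, "M", 0.0, 100.0),))


@pytest.fixture(scope="session")
def fitted2d(system2d):
    """A small fitted surrogate on the 2D demo system (12 observations)."""
    space, model = system2d
    X = random_batch(space, 12, seed=11)
    y = [
        run_virtual_sample(model, balance_counter(x, space), space, seed=100 + i).ps_fraction
        for i, x in enumerate(X)
    ]
    return fit_surrogate(X, np.array(y), space, seed=0)
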