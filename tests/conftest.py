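import numpy as np
import pytest

from stopflow import OpticalModel, RateConstants


@pytest.fixture(scope="session")
def rc():
    """The bundled experimentally determined constant set."""
    return RateConstants.abyu_defaults()


@pytest.fixture(scope="session")
def om():
    return OpticalModel()


@pytest.fixture(scope="session")
def log_grid_1000s():
    return np.geomspace(0.002, 1000.0, 3000)
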