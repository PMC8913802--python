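import numpy as np
import pytest

import koalasc as k


@pytest.fixture(scope="session")
def grid_array() -> k.DetectorArray:
    """Study-standard 5x5 detector grid at 400 m spacing."""
    return k.make_grid_array(5, 5, 400)


@pytest.fixture(scope="session")
def study_space(grid_array) -> k.StateSpace:
    """Detector envelope plus the 750 m study buffer (961 ha)."""
    return k.build_state_space(grid_array, 750)


@pytest.fixture(scope="session")
def two_detectors() -> k.DetectorArray:
    return k.DetectorArray(["a", "b"], np.array([0.0, 100.0]), np.array([0.0, 0.0]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
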