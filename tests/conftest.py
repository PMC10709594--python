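import numpy as np
import pytest

from stwarp import fixtures


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream,
    # independent of execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_points():
    return fixtures.toy_tissue()


@pytest.fixture(scope="session")
def toy_image(toy_points):
    return fixtures.toy_raster(toy_points)
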