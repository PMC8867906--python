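import numpy as np
import pytest

from brushpack.synth import experimental_brush_params, miniature_brush_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_geom():
    """Scaled-down brush (N=40, R_PS=10 nm) at the experimental grafting
    density; fast enough for free-energy sweeps in every test."""
    return miniature_brush_params()


@pytest.fixture(scope="session")
def exp_geom():
    """Full experimental dsDNA-brush geometry."""
    return experimental_brush_params()
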