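import numpy as np
import pytest

from pseudoview import make_default_setup, render_phantom_view, sample_depth_grid


@pytest.fixture(scope="session")
def setup():
    return make_default_setup()


@pytest.fixture(scope="session")
def base_view(setup):
    """Ground-truth render of the phantom at the rest viewpoint."""
    return render_phantom_view(setup)


@pytest.fixture(scope="session")
def grid5(setup):
    """Depth grid at the standard 5 mm pitch (0.2 points/mm)."""
    return sample_depth_grid(setup, 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
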