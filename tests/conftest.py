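import numpy as np
import pytest

from stimsynth import FieldGeometry, RenderContext


@pytest.fixture
def geom():
    return FieldGeometry(32, 32, frame_rate_hz=60.0)


@pytest.fixture
def ctx(geom):
    return RenderContext(geometry=geom, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
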