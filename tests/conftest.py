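import numpy as np
import pytest

from neutrotax import AssayConfig, ChannelGeometry


@pytest.fixture
def config():
    """Default assay geometry: 350 µm channel, 10 s frames, 120 frames."""
    return AssayConfig()


@pytest.fixture
def wide_config():
    """A channel so wide that wall reflections essentially never occur."""
    return AssayConfig(
        geometry=ChannelGeometry(width=5000.0), field_length=5000.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
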