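import numpy as np
import pytest
from hypothesis import settings

from standpattern.stand_model import Window
from standpattern.synthetic_stands import generate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def window50() -> Window:
    return Window(0.0, 50.0, 0.0, 50.0)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic 18-plot study at the default seed."""
    return generate_study(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
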