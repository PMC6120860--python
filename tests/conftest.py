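import numpy as np
import pytest

from octara.synthetic import ImageSpec


@pytest.fixture(scope="session")
def spec245() -> ImageSpec:
    """Default device grid: 245×245 px over 3×3 mm."""
    return ImageSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260)
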