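import numpy as np
import pytest

from conflictsim.protocol import build_regime


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unstructured_mono():
    return build_regime("monogamy", False)


@pytest.fixture
def unstructured_poly():
    return build_regime("polygamy", False)


@pytest.fixture
def structured_poly():
    return build_regime("polygamy", True)


@pytest.fixture
def structured_mono():
    return build_regime("monogamy", True)
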