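import numpy as np
import pytest

from swssre import (
    PowerSpec,
    VarianceComponents,
    tds1_design,
    tds2_design,
)


@pytest.fixture(scope="session")
def tds1():
    return tds1_design()


@pytest.fixture(scope="session")
def tds2():
    return tds2_design()


@pytest.fixture(scope="session")
def tds1_vc():
    return VarianceComponents(0.02, 0.51)


@pytest.fixture(scope="session")
def tds2_vc():
    return VarianceComponents(1.0 / 9.0, 1.0)


@pytest.fixture(scope="session")
def tds1_spec():
    return PowerSpec(alpha=0.05, beta=0.1, delta=0.2)


@pytest.fixture(scope="session")
def tds2_spec():
    return PowerSpec(alpha=0.025, beta=0.2, delta=0.267)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
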