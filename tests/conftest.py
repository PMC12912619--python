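import numpy as np
import pytest

from cerenet.atlas import default_template
from cerenet.synthetic import generate_worked_fixture


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def fixture_cohort():
    """Tiny deterministic cohort: 8 ROIs, 12 subjects per group."""
    return generate_worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
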