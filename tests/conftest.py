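import numpy as np
import pytest

from pelletcoat import doe
from pelletcoat.pipeline import REFERENCE_MODEL_COEFFICIENTS


@pytest.fixture(scope="session")
def design_table():
    return doe.load_coating_design()


@pytest.fixture(scope="session")
def fitted_model(design_table):
    return doe.fit_model(design_table)


@pytest.fixture(scope="session")
def reference_coefficients():
    return dict(REFERENCE_MODEL_COEFFICIENTS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
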