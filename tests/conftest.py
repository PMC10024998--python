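import numpy as np
import pytest

from pelletspec import make_fixture


@pytest.fixture(scope="session")
def separable():
    """Well-separated 5-species fixture (10 nm grid), SNV-preprocessed."""
    return make_fixture("separable-5species")


@pytest.fixture(scope="session")
def transfer():
    """Two-region, two-species fixture with a large regional offset."""
    return make_fixture("wf-ef-transfer")


@pytest.fixture(scope="session")
def exposure_grid():
    """Four species with intestinal + weekly-exposed (1-6) parallel samples."""
    return make_fixture("exposure-grid")


@pytest.fixture(scope="session")
def null_diet():
    """Fixture with fully overlapping diets and no diet-spectra coupling."""
    return make_fixture("null-diet")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
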