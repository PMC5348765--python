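import numpy as np
import pytest

from retromine import simulate
from retromine.pipeline import default_profiles


@pytest.fixture(scope="session")
def profiles():
    """Profiles for all ten domain families, built once per session."""
    return default_profiles()


@pytest.fixture(scope="session")
def domain_templates():
    return simulate.default_domain_templates()


@pytest.fixture(scope="session")
def element_templates():
    return simulate.default_element_templates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
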