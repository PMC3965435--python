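import pytest

from brighton.core_model import default_mapping
from brighton.guideline_engine import build_catalog
from brighton.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def original_catalog():
    return build_catalog("original")


@pytest.fixture(scope="session")
def original_cw_catalog():
    return build_catalog("original_closed_world")


@pytest.fixture(scope="session")
def updated_catalog():
    return build_catalog("updated")


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-report corpus under default noise, fixed seed."""
    return generate(SimulationConfig(n_reports=400, seed=11))
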