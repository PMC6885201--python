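import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import micmeta as mm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def studies():
    """The bundled MIC-1/T2DM study-summary table (14 studies)."""
    return mm.load_bundled_studies()


@pytest.fixture(scope="session")
def effects_d(studies):
    """Cohen's d effects for all bundled studies."""
    return [mm.smd(s, "cohen_d") for s in studies]


@pytest.fixture(scope="session")
def effects_g(studies):
    return [mm.smd(s, "hedges_g") for s in studies]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
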