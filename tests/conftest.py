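import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import selectron43 as s

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library() -> s.DatasetLibrary:
    return s.packaged_library()


@pytest.fixture(scope="session")
def bare(library) -> s.SourceDataset:
    return library["bare"]


@pytest.fixture(scope="session")
def pos1(library) -> s.SourceDataset:
    return library["pos1"]


@pytest.fixture(scope="session")
def measured(library) -> s.SourceDataset:
    return library["measured"]


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (order-independent outcomes)."""
    return np.random.Generator(np.random.PCG64(20110519))
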