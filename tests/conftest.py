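import numpy as np
import pytest
from hypothesis import settings

from coralprev import (
    ClusterParams,
    Frame,
    generate_clustered,
    generate_poisson,
    mark_random,
)

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_frame() -> Frame:
    return Frame(100.0, 100.0)


@pytest.fixture(scope="session")
def csr_pattern(small_frame):
    """A dense CSR pattern for distance-based checks."""
    return generate_poisson(small_frame, 1.0, seed=101)


@pytest.fixture(scope="session")
def clustered_pattern(small_frame):
    return generate_clustered(small_frame, ClusterParams(0.0063, 100.0, 5.0), seed=202)


@pytest.fixture(scope="session")
def study_population():
    """Full-frame R & rt population: Poisson at 0.63 /m^2, Bernoulli 0.162."""
    pattern = generate_poisson(Frame(1500.0, 200.0), 0.63, seed=42)
    return mark_random(pattern, 0.162, seed=43)


@pytest.fixture(scope="session")
def tiny_marked(small_frame):
    """A small marked pattern for survey-geometry unit tests."""
    pattern = generate_poisson(small_frame, 0.5, seed=7)
    return mark_random(pattern, 0.2, seed=8)
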