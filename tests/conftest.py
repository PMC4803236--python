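import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from traitevo import synthetic
from traitevo.io_core import parse_newick

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    return synthetic.build_fixture_bundle("tiny", seed=42)


@pytest.fixture(scope="session")
def small_tree():
    return parse_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
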