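import pytest

from gemthresh import FixtureSpec, generate_fixture, run_all


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic study: network, expression, ground truth, known pairs."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def full_table(default_fixture):
    """Binary activity table for the full 20-config sweep on the default fixture."""
    network, expr, _, _ = default_fixture
    return run_all(network, expr)
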