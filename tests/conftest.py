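import pytest

from abqsp.params import default_params


@pytest.fixture(scope="session")
def shipped():
    """Shipped calibrated (surrogate, receptor) parameter pair."""
    return default_params()


@pytest.fixture(scope="session")
def surrogate(shipped):
    return shipped[0]


@pytest.fixture(scope="session")
def receptor(shipped):
    return shipped[1]
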