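import pytest

from apoptonet import apoptosis_network, fixture_networks


@pytest.fixture(scope="session")
def apoptosis():
    return apoptosis_network()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_networks()
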