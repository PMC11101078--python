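import pytest

from pentrace import default_network, glucose_tracer


@pytest.fixture(scope="session")
def net():
    return default_network()


@pytest.fixture(scope="session")
def tracer(net):
    """Fully labeled glucose-13C6 tracer at perfect isotopic purity."""
    return glucose_tracer(net)
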