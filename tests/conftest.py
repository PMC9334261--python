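import pytest

from nanowinch import PolymerSpec, ThermalState


@pytest.fixture(scope="session")
def thermal():
    return ThermalState()


@pytest.fixture(scope="session")
def ss97():
    return PolymerSpec.ssdna(97)


@pytest.fixture(scope="session")
def ds97():
    return PolymerSpec.dsdna(97)
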