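import pytest

from floatload.config import default_trait_syntheses
from floatload.synthetic import zambezi_demo


@pytest.fixture(scope="session")
def traits():
    """Packaged default trait syntheses (biomass per area, tissue N/P)."""
    return default_trait_syntheses()


@pytest.fixture(scope="session")
def demo():
    """Observed study inputs for the four Zambezi tributaries."""
    return zambezi_demo()
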