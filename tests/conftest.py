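import pytest

from ucigen import lines
from ucigen.cross_engine import GeneticMap


@pytest.fixture(scope="session")
def registry():
    return lines.default_registry()


@pytest.fixture(scope="session")
def gmap(registry):
    return GeneticMap.from_registry(registry)


@pytest.fixture(scope="session")
def founders():
    return lines.founders()
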