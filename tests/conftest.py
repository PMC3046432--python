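import numpy as np
import pytest

from marginspec.spectral import ExtinctionBasis, default_grid
from marginspec.transport import ProbeGeometry, TransportConfig, build_lookup


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def basis(grid):
    return ExtinctionBasis.default(grid)


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def transport_config():
    return TransportConfig(seed=2)


@pytest.fixture(scope="session")
def lookup(geometry, transport_config):
    """Shared baseline lookup (built once per session, ~1 minute)."""
    return build_lookup(geometry, transport_config)
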