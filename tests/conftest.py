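import numpy as np
import pytest

from oraleis import cli_io


@pytest.fixture(scope="session")
def config():
    """Bundled default configuration (coarse mesh preset)."""
    return cli_io.default_config()


@pytest.fixture(scope="session")
def probe_freqs():
    """Small frequency set spanning the band: low, mid, high."""
    return np.array([76.0, 1.0e4, 5.0e4, 625.0e3])


@pytest.fixture(scope="session")
def toy_cell():
    return cli_io.make_fixtures("toy_cell")


@pytest.fixture(scope="session")
def toy_stack():
    return cli_io.make_fixtures("toy_stack")


@pytest.fixture(scope="session")
def oracle_block():
    return cli_io.make_fixtures("oracle_block")
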