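import numpy as np
import pytest

from gliomicro.protocol_io import paper_scheme


@pytest.fixture(scope="session")
def scheme():
    """The study protocol: b = 0, 1250, 2500 s/mm^2, 25 directions/shell."""
    return paper_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
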