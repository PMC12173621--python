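import numpy as np
import pytest

from delimech.biaxial_io import TestProtocol, load_reference_dataset

# a domain dataclass, not a test case
TestProtocol.__test__ = False


@pytest.fixture(scope="session")
def reference():
    """The packaged eight-product mean biaxial dataset."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
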