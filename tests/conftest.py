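import numpy as np
import pytest

from wrkykit.family_scan import ScanConfig


@pytest.fixture
def cfg():
    return ScanConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20170380)
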