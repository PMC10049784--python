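import numpy as np
import pytest

from haplodrop import canonical_pedigrees


@pytest.fixture(scope="session")
def pedigrees():
    return canonical_pedigrees()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231703)
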