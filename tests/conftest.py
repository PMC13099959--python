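import numpy as np
import pytest

from mfcomp import enumerate_library


@pytest.fixture(scope="session")
def full_library():
    """The complete panel: WT plus all substitutions at positions 1-8."""
    return enumerate_library()


@pytest.fixture(scope="session")
def tiny_library():
    """WT plus the 19 substitutions at position 2 (20 genotypes)."""
    return enumerate_library(variable_positions={2})


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
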