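import numpy as np
import pytest

from xciscape import synthetic_data


@pytest.fixture(scope="session")
def toy():
    """The fixed hand-checkable 8-gene / 3-TAD / 2-tissue / 2-individual bundle."""
    return synthetic_data.toy_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
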