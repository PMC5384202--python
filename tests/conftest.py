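import numpy as np
import pytest

from mitophylo.synthetic_data import make_reference


@pytest.fixture(scope="session")
def ref():
    """Small annotated reference shared across tests."""
    return make_reference(length=2000, seed=42)


@pytest.fixture(scope="session")
def big_ref():
    """Mitogenome-sized synthetic reference for dating experiments."""
    return make_reference(
        length=16569, seed=7, control=(1, 1122), gene=(1123, 14001), rrna_trna=(14002, 16000)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
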