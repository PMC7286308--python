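import numpy as np
import pytest

from bna.connectome import normalize_structural, synth_connectome


@pytest.fixture(scope="session")
def small_sn():
    """Normalized 10-region synthetic connectome."""
    return normalize_structural(synth_connectome(M=10, n_modules=2, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
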