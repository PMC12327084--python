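import numpy as np
import pytest

from dmriage.synthetic import make_scheme


@pytest.fixture(scope="session")
def camcan_scheme():
    """Two-shell scheme emulating the study design: 3 b0 + 30 directions at
    b=1 and the same 30 at b=2 ms/µm²."""
    return make_scheme(n_dirs=30, bvals=(1.0, 2.0), n_b0=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
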