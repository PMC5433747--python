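import numpy as np
import pytest

from seedshift import KernelSpec, RunConfig, build_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def kernel():
    return KernelSpec()


@pytest.fixture
def landscape(rng):
    return build_landscape(20, 50.0, 5.0, 6.0, rng)


@pytest.fixture
def reduced_config():
    """Desk-scale configuration: 60 species on 25 patches."""
    return RunConfig(n_patches=25, n_species=60, n_replicates=1, seed=7)
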