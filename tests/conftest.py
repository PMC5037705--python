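import numpy as np
import pytest

from metaboqtl.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small simulated study (97 samples, 800 SNPs)."""
    return simulate_dataset(SimConfig(n_snps=800, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
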