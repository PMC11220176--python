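import numpy as np
import pytest

from ectlnc.simulate import SimParams, generate_ect_dataset

# smaller background/decoy set than the study defaults: keeps the suite fast
# without touching the planted structure under test
FAST_SIM = dict(chrom_length=150_000, n_decoy_lncrnas=10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study's default conditions."""
    return generate_ect_dataset(SimParams(rng_seed=11))


@pytest.fixture(scope="session")
def fast_dataset():
    return generate_ect_dataset(SimParams(rng_seed=11, **FAST_SIM))
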