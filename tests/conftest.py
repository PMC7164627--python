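import numpy as np
import pytest

from skewtgmm import StartPolicy, default_growth_params, generate_dataset
from skewtgmm.nonnormal import NonnormalSpec


@pytest.fixture(scope="session")
def growth():
    return default_growth_params()


@pytest.fixture(scope="session")
def normal_data_200(growth):
    """One N=200 dataset from the normal condition."""
    return generate_dataset(growth, NonnormalSpec(0, 0), 200, seed=20)


@pytest.fixture(scope="session")
def quick_starts(growth):
    """Reduced multistart policy for unit tests (speed over exhaustiveness)."""
    return StartPolicy(n_random=8, n_final=2, initial_iters=10, base=growth)
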