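import numpy as np
import pytest

from saxsbme import generate_chain_ensemble, make_truth_case, saxs_observable_matrix


@pytest.fixture(scope="session")
def chain_ensemble():
    """A small unbiased self-avoiding chain ensemble (200 frames, 30 residues)."""
    return generate_chain_ensemble(200, 30, seed=5)


@pytest.fixture(scope="session")
def truth_case(chain_ensemble):
    """Synthetic SAXS/PRE data from an expansion-tilted truth on the chain ensemble."""
    return make_truth_case(chain_ensemble, kappa=0.2, seed=6)


@pytest.fixture(scope="session")
def observable_matrix(chain_ensemble, truth_case):
    return saxs_observable_matrix(chain_ensemble, truth_case.synthetic_saxs.q)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
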