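import numpy as np
import pytest
from hypothesis import settings

import riailmap as rm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel296() -> rm.GenotypeMatrix:
    """296-strain recombinant panel on the default 1,690-cM six-chromosome map."""
    return rm.simulate_riail_panel(296, seed=11)


@pytest.fixture(scope="session")
def kernel296(panel296):
    return rm.additive_kernel(panel296)


@pytest.fixture(scope="session")
def kernel_chol(kernel296):
    """Factor L with L L' = A (+tiny jitter), for drawing kernel-structured effects."""
    A = kernel296.to_numpy()
    evals, evecs = np.linalg.eigh(A + 1e-8 * np.eye(len(A)))
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


@pytest.fixture(scope="session")
def interaction_chol(kernel296):
    AI = (kernel296 * kernel296).to_numpy()
    evals, evecs = np.linalg.eigh(AI + 1e-8 * np.eye(len(AI)))
    return evecs * np.sqrt(np.clip(evals, 0.0, None))
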