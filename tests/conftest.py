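import numpy as np
import pytest
from hypothesis import settings

from epicoherence.synthetic import ScJointSpec, simulate_sc_joint

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_joint():
    """A small admixture single-cell dataset shared across MI/entropy tests."""
    spec = ScJointSpec(n_cells=60, n_genes=200, coupling=8.0,
                       heterogeneity_mode="admixture", seed=11)
    return simulate_sc_joint(spec)
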