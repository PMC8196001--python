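import numpy as np
import pytest

from bilicausal import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """A modest structured cohort shared across test modules."""
    cfg = simdata.SimConfig(n_samples=400, n_variants=600, causal_index=300, seed=11)
    return simdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def plain_genotypes():
    """Unstructured, unrelated, LD-free genotypes (independence baseline)."""
    cfg = simdata.SimConfig(
        n_samples=500, n_variants=800, causal_index=400, seed=5,
        fst=0.0, n_subpops=1, n_sib_pairs=0, within_block_rho=0.0,
    )
    return simdata.simulate_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
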