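import numpy as np
import pytest

from vhlkit import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free 30-sample cohort with a clonal one-copy loss + het mutation."""
    spec = simulate.CohortSpec(n_samples=30, cnr_noise_sd=0.0, vaf_noise_sd=0.0,
                               purity_obs_sd=0.0, seed=7)
    return simulate.simulate_tumor_cohort(spec)


@pytest.fixture(scope="session")
def infiltration_tissue():
    spec = simulate.default_infiltration_tissue(seed=3)
    return simulate.simulate_tissue(spec)
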