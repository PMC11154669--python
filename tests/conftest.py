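import numpy as np
import pytest

from plierlite import generate_compendium, generate_prior


@pytest.fixture(scope="session")
def small_prior():
    """5 disjoint 10-gene sets over 100 genes."""
    prior, hierarchy = generate_prior(n_genes=100, n_sets=5, genes_per_set=10, seed=7)
    return prior, hierarchy


@pytest.fixture(scope="session")
def small_compendium(small_prior):
    """100-gene / 6-LV / 4-study compendium with 4 prior-aligned LVs."""
    prior, _ = small_prior
    expr, meta, truth = generate_compendium(
        prior, n_lvs=6, n_prior_aligned=4, studies=4, samples_per_study=20,
        noise_sd=0.3, seed=21,
    )
    return expr, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
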