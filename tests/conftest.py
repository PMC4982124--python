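import numpy as np
import pytest

from familyscope.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact noise-free dataset with decoy tiers, shared per session."""
    cfg = GeneratorConfig(seed=11, n_families=6,
                          members_per_family_range=(2, 3),
                          n_chromosomes=2, chromosome_length=3_000_000,
                          n_tm_kinase_decoys=3, n_kinase_decoys=3)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same shape with 5 % nucleotide substitution noise."""
    cfg = GeneratorConfig(seed=12, n_families=6,
                          members_per_family_range=(2, 3),
                          n_chromosomes=2, chromosome_length=3_000_000,
                          mutation_rate=0.05)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
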