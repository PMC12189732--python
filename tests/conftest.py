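import numpy as np
import pytest

import crossdti as cd
from crossdti.model import ModelConfig, init_model


@pytest.fixture(scope="session")
def small_data():
    """A small planted-structure dataset shared by training/eval tests."""
    spec = cd.SyntheticSpec(n_targets=12, n_compounds=60, noise_rate=0.0, seed=5)
    return cd.generate_synthetic_dti(spec)


@pytest.fixture(scope="session")
def small_features(small_data):
    dataset, _ = small_data
    config = cd.FeaturizeConfig(fingerprint_bits=256, kmer_dim=16, kmer_epochs=2, seed=5)
    return cd.featurize_dataset(dataset.compounds.values(), dataset.targets.values(), config)


@pytest.fixture
def tiny_state():
    """A shape-consistent random model small enough for brute-force oracles."""
    cfg = ModelConfig(target_dim=5, compound_dim=6, p=8, hidden=7, token_count=1, seed=3)
    return init_model(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
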