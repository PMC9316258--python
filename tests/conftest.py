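import numpy as np
import pytest

import sagpred as sp


@pytest.fixture(scope="session")
def default_spec() -> sp.EncodingSpec:
    return sp.EncodingSpec()


@pytest.fixture(scope="session")
def strong_dataset():
    """Divergence-3 benchmark: clearly separable two-class set, n = 200."""
    config = sp.SimulationConfig(n_pos=100, n_neg=100, divergence=3.0, seed=11)
    records, labels = sp.generate(config)
    return records, labels


@pytest.fixture(scope="session")
def strong_features(strong_dataset, default_spec):
    records, labels = strong_dataset
    return sp.encode_matrix(records, default_spec), labels


@pytest.fixture(scope="session")
def svm_fixed_config() -> sp.ModelConfig:
    return sp.ModelConfig(
        family="svm",
        seed=17,
        fixed_params={"cost": 1.0, "gamma": "scale", "kernel": "rbf"},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220705)
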