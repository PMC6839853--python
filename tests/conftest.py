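import numpy as np
import pytest

from mitonet import GenerationConfig, generate_all


@pytest.fixture(scope="session")
def default_config() -> GenerationConfig:
    return GenerationConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic_study(default_config):
    """One fully generated synthetic study shared across tests."""
    truth, sources, datasets, annotations = generate_all(default_config)
    return {
        "config": default_config,
        "truth": truth,
        "sources": sources,
        "datasets": datasets,
        "annotations": annotations,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
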