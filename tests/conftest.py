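import numpy as np
import pytest

from fedcmc import CenterDataset, GeneratorConfig, generate_federation
from fedcmc.network import ConvNet, ConvNetConfig


@pytest.fixture(scope="session")
def small_federation():
    """Three small heterogeneous centers with planted clones (session-cached)."""
    cfg = GeneratorConfig(
        per_center_n=(60, 40, 20),
        prevalence=(0.8, 0.85, 0.8),
        heterogeneity_shift=(0.0, 0.1, 0.2),
        clone_fraction=(0.3, 0.4, 0.1),
        seed=11,
    )
    return generate_federation(cfg)


@pytest.fixture(scope="session")
def tiny_net():
    return ConvNet(ConvNetConfig(image_size=(16, 16)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
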