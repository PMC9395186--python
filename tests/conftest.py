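import numpy as np
import pytest

from swingan.swin_core import SwinConfig
from swingan.generator import GeneratorConfig
from swingan.registration import STRConfig
from swingan.adversarial import DiscriminatorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_swin():
    return SwinConfig(window_size=4, embed_dim=8, num_heads=2)


@pytest.fixture
def tiny_generator():
    return GeneratorConfig(
        n_rstb=2, n_stl_per_rstb=2,
        swin=SwinConfig(window_size=4, embed_dim=8, num_heads=2),
    )


@pytest.fixture
def tiny_str():
    return STRConfig(levels=3, base_channels=4, n_stl_encoder=1)


@pytest.fixture
def tiny_disc():
    return DiscriminatorConfig(n_layers=2, base_channels=8)
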