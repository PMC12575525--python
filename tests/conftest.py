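import numpy as np
import pytest

from dzseg.model import TINY_PRESET, DecoderConfig, EncoderConfig, LoRAConfig, build_model


@pytest.fixture
def tiny_configs():
    return (EncoderConfig(**TINY_PRESET["enc"]), LoRAConfig(rank=4),
            DecoderConfig(**TINY_PRESET["dec"]))


@pytest.fixture
def tiny_model(tiny_configs):
    enc, lora, dec = tiny_configs
    return build_model(enc, lora, dec, seed=0)


@pytest.fixture
def disk_mask():
    """A 32x32 mask with a radius-10 dissection-zone disk."""
    rr, cc = np.mgrid[0:32, 0:32]
    return ((rr - 16) ** 2 + (cc - 16) ** 2 <= 100).astype(np.uint8)
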