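import numpy as np
import pytest

from cardiofuse import PRESETS, SynthParams, build_dataset, synth_dataset
from cardiofuse.network import ModelConfig

# Reduced-width configuration used for training experiments: the same
# architecture (four levels, strides 1/5/5/5, SE-ResNet blocks, SACMF
# chain) at channels 8/16/24/32 and 500-sample inputs, sized for a
# single CPU.
SMALL_NET = dict(
    input_len=500, channels=(8, 16, 24, 32), se_ratio=4,
    spatial_reduce=4, channel_ratio=4, head_hidden=(32, 16, 8),
)


def small_config(**overrides) -> ModelConfig:
    kw = dict(SMALL_NET)
    kw.update(overrides)
    return ModelConfig(**kw)


@pytest.fixture(scope="session")
def easy_dataset():
    """Strongly class-separated segments (both modalities informative)."""
    records = synth_dataset(20, PRESETS["easy"], seed=42)
    return build_dataset(records)


@pytest.fixture(scope="session")
def easy_arrays(easy_dataset):
    return easy_dataset.arrays(SMALL_NET["input_len"])


@pytest.fixture()
def default_params():
    return SynthParams(seed=7)
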