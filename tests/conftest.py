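import numpy as np
import pytest

from cenland.core_io import PipelineConfig
from cenland.synthetic_data import random_dna


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def consensus_156(rng):
    return random_dna(156, rng)
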