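import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chromanose import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def default_model():
    """The default 12-dye response model at the study's noise level."""
    return synthgen.DyeResponseModel.default(seed=7)


@pytest.fixture
def noiseless_model():
    return synthgen.DyeResponseModel.default(seed=7, noise_sd=0.0)


@pytest.fixture
def study_dataset(default_model):
    """84 samples: 6 levels × 14 replicates, default noise."""
    return synthgen.generate_dataset(model=default_model, seed=7)
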