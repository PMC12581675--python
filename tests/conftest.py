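import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ramanfp import CohortDesign, NoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_design():
    """1 sample per cell, 2 replicates: fast but structurally complete."""
    return CohortDesign(seed=11, samples_per_cell=1, replicates_per_sample=2)


@pytest.fixture
def noiseless_design():
    return CohortDesign(
        seed=7, samples_per_cell=1, replicates_per_sample=2, noise=NoiseSpec(0, 0, 0, 0)
    )
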