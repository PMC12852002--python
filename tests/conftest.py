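import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pcgstack import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_dataset():
    """12 subjects/class, 3 segments, 5-s recordings, strong class effect."""
    cfg = SimulationConfig(n_subjects_per_class=12, segments_per_subject=3,
                           duration_s=5.0, effect_size=2.0, noise_sd=0.05,
                           seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def random_quantized_images(rng):
    """100 random 32x32 images quantized to 32 levels (shared across tests)."""
    from pcgstack.texture import quantize

    return [quantize(rng.random((32, 32)), 32) for _ in range(100)]
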