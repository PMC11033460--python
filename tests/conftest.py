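import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(20240408)


@pytest.fixture
def disk64():
    """Filled discrete disk of radius 10 centered in a 64x64 grid."""
    yy, xx = np.mgrid[:64, :64]
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 100


@pytest.fixture
def tiny_lung_dataset():
    """Six 32x32 lung phantoms with a 2/2/2 split (fast pipeline smoke)."""
    from ugls.synthetic import PhantomSpec, generate_dataset

    spec = PhantomSpec(kind="lungs", size=32, noise_sd=0.05)
    return generate_dataset(6, spec, seed=42)


@pytest.fixture
def fast_cfg():
    from ugls.training import TrainConfig

    return TrainConfig(
        max_epochs=2, patience=2, batch_size=4, r_m=4, seed=0,
        base_filters=4, depth=2,
    )
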