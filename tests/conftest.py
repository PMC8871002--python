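import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from saxseg.phantom import PhantomParams, generate_dataset


@pytest.fixture
def small_params():
    """Phantom geometry scaled down to 64x48 for fast tests."""
    return PhantomParams(
        height=64,
        width=48,
        cavity_radius_range=(6.0, 12.0),
        myo_thickness_range=(3.0, 6.0),
        center_jitter=4.0,
    )


@pytest.fixture
def tiny_params():
    """32x24 phantoms for the cheapest training smoke tests."""
    return PhantomParams(
        height=32,
        width=24,
        cavity_radius_range=(4.0, 6.0),
        myo_thickness_range=(2.0, 3.0),
        center_jitter=2.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    params = PhantomParams(
        height=64,
        width=48,
        cavity_radius_range=(6.0, 12.0),
        myo_thickness_range=(3.0, 6.0),
        center_jitter=4.0,
    )
    return generate_dataset(40, params, seed=99)
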