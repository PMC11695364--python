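import numpy as np
import pytest

from cestq.core import build_default_offset_schedule
from cestq.lorentzian import LorentzianLine
from cestq.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def schedule():
    return build_default_offset_schedule()


@pytest.fixture(scope="session")
def offsets(schedule):
    return schedule.sampled_offsets


@pytest.fixture(scope="session")
def background_pools():
    """Water + MT only (no CEST pools)."""
    return {
        "ds": LorentzianLine(0.8, 2.0, 0.0),
        "mt": LorentzianLine(0.14, 40.0, -1.0),
    }


@pytest.fixture(scope="session")
def five_pools(background_pools):
    return {
        **background_pools,
        "amide": LorentzianLine(0.055, 1.5, 3.5),
        "amine": LorentzianLine(0.020, 1.8, 2.0),
        "noe": LorentzianLine(0.055, 3.0, -3.5),
    }


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free phantom, flat B0."""
    return generate_phantom(PhantomConfig(grid_shape=(8, 8), noise_sd=0.0,
                                          b0_field="none", seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
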