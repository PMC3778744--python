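import numpy as np
import pytest

from perfquant.engine import RunConfig
from perfquant.synth import PHANTOM_MASK_FRAC, build_phantom, preset_spec


@pytest.fixture(scope="session")
def tiny_phantom():
    """Noise-free 16x16x2x40 phantom with two tissue classes and an arterial strip."""
    return build_phantom(preset_spec("tiny"))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with Gaussian noise at 5% of the peak tissue signal."""
    return build_phantom(preset_spec("tiny", seed=7, noise_frac_of_peak=0.05))


def phantom_config(**overrides) -> RunConfig:
    """RunConfig suited to zero-background phantoms (low mask fraction)."""
    kwargs = dict(mask_frac=PHANTOM_MASK_FRAC)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
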