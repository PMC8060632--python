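import numpy as np
import pytest

from wheatcc import ImageSceneConfig, TrialConfig, generate_canopy_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_trial_config():
    """Small noiseless trial: exact power-law structure, fast to fit."""
    return TrialConfig(noise_cv=0.0, seed=11)


@pytest.fixture
def noisy_trial_config():
    return TrialConfig(noise_cv=0.1, seed=11)


@pytest.fixture
def scene_042():
    """A mid-cover synthetic scene with its exact ground-truth mask."""
    cfg = ImageSceneConfig(width=320, height=240, target_cover=0.42, seed=9)
    img, mask = generate_canopy_image(cfg)
    return cfg, img, mask
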