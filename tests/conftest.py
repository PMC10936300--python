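import numpy as np
import pytest

from sonomoment import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """Full 5-speed, 8-cycle dataset at a reduced 100 Hz clock, signals only."""
    cfg = sd.SyntheticConfig(fs_analog=100.0, fps_us=100.0, seed=7)
    return sd.gen_walking_dataset(cfg, with_images=False)


@pytest.fixture(scope="session")
def imaging_dataset():
    """Tiny dataset with 64x64 image frames for training/IO tests."""
    cfg = sd.SyntheticConfig(
        speeds=(0.50, 1.00),
        cycles_per_speed=2,
        fs_analog=40.0,
        fps_us=40.0,
        image_height_px=64,
        image_width_px=64,
        seed=11,
    )
    return sd.gen_walking_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
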