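import numpy as np
import pytest

from ssapipe.config import PipelineConfig
from ssapipe.stimulus import make_train
from ssapipe.synth import SynthParams

# reduced field of view used throughout the tests to keep movie rendering
# fast; blob geometry scales with it
SMALL_GEOM = dict(
    image_shape=(60, 80),
    blob_centers=((30.0, 20.0), (30.0, 60.0)),
    blob_sigma_px=8.0,
)


@pytest.fixture
def train_1hz():
    return make_train(1.0, 10, 8000.0, 16000.0)


@pytest.fixture
def train_4hz():
    return make_train(4.0, 10, 8000.0, 16000.0)


@pytest.fixture
def small_params():
    return SynthParams(**SMALL_GEOM)


@pytest.fixture
def noiseless_params():
    return SynthParams(
        noise_sd=0.0, anatomy_amp=0.0, bleach_tau_s=1e12, **SMALL_GEOM
    )


def small_config(**synth_overrides) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.synth.image_shape = [60, 80]
    cfg.synth.blob_centers = [[30.0, 20.0], [30.0, 60.0]]
    cfg.synth.blob_sigma_px = 8.0
    for key, value in synth_overrides.items():
        setattr(cfg.synth, key, value)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
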