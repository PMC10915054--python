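import numpy as np
import pytest

from thermoleaf import LeafSceneSpec, generate_leaf_scene
from thermoleaf.io import ThermalFrame


@pytest.fixture
def noiseless_scene():
    """Sharp-edged leaf at 27 °C on a 22 °C backdrop, no noise or blur."""
    spec = LeafSceneSpec(
        noise_sd=0.0,
        blur_sigma=0.0,
        leaf_temp_sd=0.0,
        gradient_amplitude=0.0,
        background_temp=22.0,
        leaf_temp_mean=27.0,
        seed=0,
    )
    return generate_leaf_scene(spec)


@pytest.fixture
def noisy_scene():
    """Realistic scene: 5 °C contrast, 1-px optics blur, 0.2 °C sensor noise."""
    spec = LeafSceneSpec(
        noise_sd=0.2,
        blur_sigma=1.0,
        background_temp=22.0,
        leaf_temp_mean=27.0,
        seed=1,
    )
    return generate_leaf_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_frame(values, **meta) -> ThermalFrame:
    return ThermalFrame(np.asarray(values, float), sample_id="test", metadata=meta)
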