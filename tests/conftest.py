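import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specreflow as sr
from specreflow.preprocess import enhance_frame
from specreflow.unet import LightUNet, TrainConfig, train_light_unet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tissue_frame():
    """One clean 64x64 synthetic tissue frame."""
    cfg = sr.SceneConfig(height=64, width=64, n_frames=1, motion_model="static",
                         noise_sigma=2, seed=7)
    return sr.generate_tissue_sequence(cfg)[0]


@pytest.fixture(scope="session")
def corrupted_frame_and_mask(tissue_frame):
    corr, masks = sr.synthesize_sr_artifacts(
        tissue_frame[None], sr.SRArtifactConfig(n_regions=2, seed=3)
    )
    return corr[0], masks[0]


def _synthetic_pairs(n_scenes, frames_per_scene, seed0):
    """(enhanced frame, core mask) pairs from corrupted synthetic tissue."""
    pairs = []
    for s in range(n_scenes):
        cfg = sr.SceneConfig(height=64, width=64, n_frames=frames_per_scene,
                             motion_model="translation", motion_magnitude=1,
                             noise_sigma=2, seed=seed0 + s)
        clean = sr.generate_tissue_sequence(cfg)
        corr, masks = sr.synthesize_sr_artifacts(
            clean, sr.SRArtifactConfig(n_regions=3, seed=seed0 + 100 + s)
        )
        pairs.extend((enhance_frame(f), m) for f, m in zip(corr, masks))
    return pairs


@pytest.fixture(scope="session")
def training_pairs():
    return _synthetic_pairs(n_scenes=5, frames_per_scene=10, seed0=0)


@pytest.fixture(scope="session")
def heldout_pairs():
    return _synthetic_pairs(n_scenes=1, frames_per_scene=10, seed0=50)


@pytest.fixture(scope="session")
def trained_model(training_pairs, heldout_pairs):
    """Light U-net trained on 50 synthetic pairs; shared across tests."""
    model = LightUNet(seed=0)
    model, history = train_light_unet(
        model, training_pairs, TrainConfig(epochs=25, seed=0),
        val_dataset=heldout_pairs,
    )
    return model, history
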