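import numpy as np
import pytest

from thermaltrack.synthetic import (
    DetectorNoiseModel,
    SceneConfig,
    generate_survey,
    run_mock_detector,
)

#: compact survey used by most integration tests: one straight east-west
#: transect, coarse GSD so camera motion is ~3 px/frame
SMALL_SCENE = dict(
    extent_m=(80.0, 60.0),
    frame_shape=(144, 192),
    gsd_m_per_px=0.3,
    n_frames=40,
    n_animals=5,
    n_kangaroos=1,
    heading_jitter_deg=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_survey(SceneConfig(**SMALL_SCENE))


@pytest.fixture(scope="session")
def noise_free_bundle():
    cfg = SceneConfig(**{**SMALL_SCENE, "n_kangaroos": 0, "sensor_noise_std": 0.0})
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def noise_free_detections(noise_free_bundle):
    """Two perfect mock detectors on the noise-free scene."""
    return [
        run_mock_detector(noise_free_bundle, DetectorNoiseModel(detector_id=f"d{k}", seed=k))
        for k in (1, 2)
    ]
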