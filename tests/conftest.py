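import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from nirtcal.simulator import SimulationConfig  # noqa: E402

# A small sensor keeps simulated grids fast while leaving enough ROI pixels
# (64 per trace area) for the 10% spatial trim to act on.
SMALL_SENSOR = dict(
    frame_shape=(24, 48),
    rois={"object": (4, 12, 4, 12), "reference": (4, 12, 28, 36)},
)


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Error-free camera on a small sensor, short capture."""
    return SimulationConfig(n_frames=20, **SMALL_SENSOR).clean()


@pytest.fixture
def noisy_config(clean_config) -> SimulationConfig:
    """Default-magnitude detector errors on the small sensor."""
    return dataclasses.replace(
        clean_config,
        gain=1.08,
        offset=0.3,
        drift_amplitude=2.0,
        netd_c=0.05,
        thermistor_noise_c=0.01,
        n_frames=60,
    )
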