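import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from matiss.config import CampaignConfig, ImagingGeometry, SizeModel  # noqa: E402
from matiss.frames import FrameStack  # noqa: E402


@pytest.fixture(scope="session")
def tiny_config() -> CampaignConfig:
    """A desk-scale campaign small enough for per-test simulation."""
    return CampaignConfig(
        name="tiny",
        exposure_days=100,
        occupancy_rate=1.0,
        coarse_density=2.0,
        fine_density=4.0,
        macro_rate=0.0,
        window_um=2000.0,
        imaging_low=ImagingGeometry(2.0, (500, 500), (2, 2)),
        imaging_high=ImagingGeometry(0.35, (512, 512), (2, 2)),
        seed=1234,
    )


def make_stack(frames: np.ndarray, zoom="high", pixel_size=0.35, bit_depth=8) -> FrameStack:
    """FrameStack from a (n, r, c) grey array, frames tiled along y."""
    frames = np.asarray(frames)
    rgb = np.repeat(frames[..., None], 3, axis=-1)
    n, r, c = frames.shape
    origins = np.column_stack(
        [np.zeros(n), np.arange(n) * r * pixel_size]
    )
    return FrameStack(
        frames=rgb,
        zoom=zoom,
        pixel_size_um=pixel_size,
        frame_origins=origins,
        bit_depth=bit_depth,
    )


@pytest.fixture
def grey_stack_factory():
    return make_stack
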