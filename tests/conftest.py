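import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swimscore import SyntheticSchedule, render_video

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("videos")


@pytest.fixture(scope="session")
def short_schedule():
    """20 s alternating 5-s mobile/immobile blocks."""
    return SyntheticSchedule.alternating(20, period_s=5)


@pytest.fixture(scope="session")
def short_video(fixture_dir, short_schedule):
    """Rendered 20-s, 15-fps fixture (video path, truth CSV path)."""
    return render_video(
        short_schedule, fixture_dir / "short.avi", fps=15.0, seed=7
    )


@pytest.fixture(scope="session")
def static_video(fixture_dir):
    """Noise-free all-immobile 10-s fixture: every frame identical."""
    schedule = SyntheticSchedule.constant(10, immobile=True)
    return render_video(
        schedule, fixture_dir / "static.avi", fps=15.0, noise_sd=0.0, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
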