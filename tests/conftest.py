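import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from chromotrack.io import CellVideo, FRAME_COLUMNS

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def build_video(green, red, times=None, intensity=40.0, contrast=20.0,
                video_id="v0", cell_id=None, strain_id="strain0",
                role="unpaired", pair_id=None, stack_range=(0.0, 5000.0),
                frame_interval=1.0,
                intensity_green=None, intensity_red=None,
                contrast_green=None, contrast_red=None) -> CellVideo:
    """Construct a CellVideo from coordinate arrays with uniform covariates."""
    green = np.atleast_2d(np.asarray(green, dtype=float))
    red = np.atleast_2d(np.asarray(red, dtype=float))
    n = len(green)
    if times is None:
        times = np.arange(n, dtype=float) * frame_interval

    def fill(value, default):
        if value is None:
            value = default
        return np.full(n, value, dtype=float) if np.isscalar(value) else np.asarray(value, dtype=float)

    frames = pd.DataFrame({
        "time_s": np.asarray(times, dtype=float),
        "x_nm_green": green[:, 0], "y_nm_green": green[:, 1], "z_nm_green": green[:, 2],
        "intensity_green": fill(intensity_green, intensity),
        "contrast_green": fill(contrast_green, contrast),
        "x_nm_red": red[:, 0], "y_nm_red": red[:, 1], "z_nm_red": red[:, 2],
        "intensity_red": fill(intensity_red, intensity),
        "contrast_red": fill(contrast_red, contrast),
    })[FRAME_COLUMNS]
    return CellVideo(video_id=video_id, cell_id=cell_id or video_id,
                     strain_id=strain_id, role=role, pair_id=pair_id,
                     frame_interval=frame_interval, stack_range=stack_range,
                     frames=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
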