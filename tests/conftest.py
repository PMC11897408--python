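import numpy as np
import pytest

from decondenseq.segmentation import ChromatinObject
from decondenseq.synthetic import (
    MassParams,
    TimelapseParams,
    TwoChannelParams,
    make_chromatin_mass,
    make_decondensation_timelapse,
    make_two_channel_cell,
)


def make_object(area: float, centroid: tuple[float, float], frame_index: int = 0):
    """Lightweight stand-in object for rule-level tests (no pixel mask)."""
    return ChromatinObject(
        mask=np.zeros((1, 1), dtype=bool),
        area_px2=int(area),
        area_um2=float(area),
        centroid=centroid,
        frame_index=frame_index,
    )


@pytest.fixture
def disk_mass():
    """Noise-free perfect disk, R=50."""
    params = MassParams(
        image_size_px=(160, 160), radius_px=50, roughness_amplitude=0.0, seed=0
    )
    return make_chromatin_mass(params)


@pytest.fixture
def rough_mass():
    """Condensed-cluster-like mass, a=0.3."""
    params = MassParams(
        image_size_px=(160, 160), radius_px=50, roughness_amplitude=0.3, seed=3
    )
    return make_chromatin_mass(params)


@pytest.fixture
def clean_lapse():
    """Noise-free mitotic time-lapse, onset at frame 8."""
    params = TimelapseParams(seed=11, noise_sd=0.0, blur_sigma_px=0.0)
    return make_decondensation_timelapse(params)


@pytest.fixture
def two_channel_cell():
    """Noise-free two-channel cell with 3 bright foci."""
    params = TwoChannelParams(
        n_foci=3, focus_intensity=150.0, cytoplasm_intensity=30.0, seed=7
    )
    return make_two_channel_cell(params)
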