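import numpy as np
import pytest

from carpalign.phantom import DEFAULT_ANGLE_MEANS, PoseConfig, generate_phantom
from carpalign.projection import define_spc_lateral_plane


@pytest.fixture(scope="session")
def neutral_phantom():
    """Neutral wrist: all pose angles zero."""
    ph = generate_phantom(PoseConfig(), seed=0)
    ph.volume  # realize the voxel grid once for the whole session
    return ph


@pytest.fixture(scope="session")
def posed_phantom():
    """Wrist posed at the cohort default mean angles."""
    ph = generate_phantom(PoseConfig(angles=DEFAULT_ANGLE_MEANS), seed=0)
    ph.volume
    return ph


@pytest.fixture(scope="session")
def neutral_plane(neutral_phantom):
    return define_spc_lateral_plane(neutral_phantom.volume)


@pytest.fixture(scope="session")
def posed_plane(posed_phantom):
    return define_spc_lateral_plane(posed_phantom.volume)


def in_plane_angle(direction: np.ndarray) -> float:
    """Signed lateral-plane angle (deg) of a world direction, flexion +."""
    return float(np.degrees(np.arctan2(direction[1], direction[2])))
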