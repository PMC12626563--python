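import numpy as np
import pytest

import vesselcad as vc
from vesselcad.phantoms import WRAP_VESSEL_LENGTH, WRAP_VESSEL_RADIUS


def digital_ball(r: float, n: int | None = None, center=None) -> np.ndarray:
    """Binary ball of radius r voxels on an n^3 grid."""
    if n is None:
        n = int(2 * r + 8)
    if center is None:
        center = ((n - 1) / 2.0,) * 3
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        <= r * r
    )


@pytest.fixture(scope="session")
def straight_tube():
    mask, truth = vc.make_vessel_phantom("straight", length=60, radius_profile=4)
    return mask, truth


@pytest.fixture(scope="session")
def straight_tube_skeleton(straight_tube):
    mask, _ = straight_tube
    return vc.skeletonize_graph(mask)


@pytest.fixture(scope="session")
def y_tube():
    mask, truth = vc.make_vessel_phantom("Y", length=60, radius_profile=4)
    return mask, truth


@pytest.fixture(scope="session")
def wrap_vessel():
    """Large-caliber straight tube used by the encasement-angle phantoms."""
    mask, truth = vc.make_vessel_phantom(
        "straight", length=WRAP_VESSEL_LENGTH,
        radius_profile=WRAP_VESSEL_RADIUS, grid=96,
    )
    return mask, truth


@pytest.fixture(scope="session")
def two_vessel_scene():
    return vc.make_scene(n_vessels=2, seed=3)
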