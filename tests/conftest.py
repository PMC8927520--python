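import numpy as np
import pytest

from petmrac import (
    AnatomyConfig,
    AttenuationMap,
    Geometry,
    LesionSpec,
    make_phantom,
    reference_attenuation_map,
)


def antialiased_disk(n: int, pixel_mm: float, radius_mm: float, ss: int = 4) -> np.ndarray:
    """Disk indicator with partial-volume (area-fraction) edge voxels."""
    c = (n - 1) / 2.0
    off = (np.arange(ss) + 0.5) / ss - 0.5
    acc = np.zeros((n, n))
    for ox in off:
        for oy in off:
            x = (np.arange(n) - c + ox) * pixel_mm
            y = (np.arange(n) - c + oy) * pixel_mm
            acc += x[:, None] ** 2 + y[None, :] ** 2 <= radius_mm**2
    return acc / ss**2


@pytest.fixture(scope="session")
def phantom():
    """Default-anatomy phantom at the cohort grid, fixed seed."""
    return make_phantom((64, 64, 16), (3.0, 3.0, 3.0), seed=7)


@pytest.fixture(scope="session")
def ref_map(phantom):
    return reference_attenuation_map(phantom)


@pytest.fixture(scope="session")
def geom():
    return Geometry(nx=64, ny=64, pixel_mm=3.0, n_angles=84)


@pytest.fixture(scope="session")
def water_disk(geom):
    """Unit-activity water disk (antialiased) on the cohort slice grid."""
    from petmrac.attenuation import WATER_LAC

    disk = antialiased_disk(geom.nx, geom.pixel_mm, 80.0)
    act = disk[:, :, None]
    mu = AttenuationMap(lac=WATER_LAC * disk[:, :, None], spacing=(3.0, 3.0, 3.0))
    return act, mu, disk > 0.5


@pytest.fixture
def small_anatomy():
    """Compact anatomy that fits a 120 mm field of view, without jitter."""
    return AnatomyConfig(
        body_semiaxes_mm=(50.0, 45.0),
        spine_center_mm=(0.0, 25.0),
        trachea_center_mm=(0.0, -15.0),
        oral_center_mm=(0.0, -12.0),
        oral_radius_mm=5.0,
        esophagus_center_mm=(0.0, 5.0),
        mandible_radius_mm=30.0,
        lesions=(LesionSpec(center_mm=(-20.0, 0.0, 0.5), diameter_mm=10.0, suv=5.0),),
        jitter=0.0,
    )
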