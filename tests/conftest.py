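import numpy as np
import pytest

from hefq.core import ScanGeometry
from hefq.synth import VolumeParams, generate_volume


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    """Reduced-resolution geometry over the standard 6 x 6 x 2 mm field."""
    return ScanGeometry(n_ascans=96, n_bscans=16, n_axial=128)


@pytest.fixture(scope="session")
def default_volume(small_geom):
    """One synthetic volume at default parameters with its truth."""
    return generate_volume(small_geom, VolumeParams(n_blobs=8), seed=7)


@pytest.fixture(scope="session")
def clean_volume(small_geom):
    """Noise-free two-layer volume without blobs or fluid."""
    params = VolumeParams(n_blobs=0, n_fluid=0, noise_sd=0.0)
    return generate_volume(small_geom, params, seed=3)


def random_mask(geometry: ScanGeometry, density: float, rng: np.random.Generator):
    from hefq.core import HRFMask

    return HRFMask(
        mask=rng.random(geometry.shape) < density, geometry=geometry
    )
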