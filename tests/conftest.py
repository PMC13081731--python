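import numpy as np
import pytest

from biodscore import Zonation, disk_boundary

DISK_RADIUS_UM = 1000.0


@pytest.fixture(scope="session")
def disk():
    """Polygonal disk of radius 1 mm — the canonical zonation fixture."""
    return disk_boundary(DISK_RADIUS_UM, n_vertices=512)


@pytest.fixture(scope="session")
def disk_zonation(disk):
    """Zonation of the disk at the default 4 µm / 10 zones."""
    return Zonation(pixel_size=4.0, n_zones=10).fit(disk)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
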