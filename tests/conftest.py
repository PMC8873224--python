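import pytest

from fundusdr.fundus_model import FundusGeometry
from fundusdr.synthetic_data import default_geometry


@pytest.fixture
def geometry() -> FundusGeometry:
    """Canonical macula-centred frame (1200x1200 px, 120 px disc)."""
    return default_geometry()


@pytest.fixture
def unit_geometry() -> FundusGeometry:
    """Fovea at origin, disc diameter 100 px: DD distances are d/100."""
    return FundusGeometry(disc_centre=(250.0, 0.0), disc_diameter=100.0,
                          fovea_centre=(0.0, 0.0))


@pytest.fixture
def small_geometry() -> FundusGeometry:
    """Small frame used for raster phantoms (400x400 px, 40 px disc)."""
    return default_geometry(400, 400, 40.0)
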