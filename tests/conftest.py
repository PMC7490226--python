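import numpy as np
import pytest

from drasdo import build_eye
from drasdo.density_maps import synthetic_density
from drasdo.displacement import build_displacement_field
from drasdo.fixtures import make_selfconsistent_density


@pytest.fixture(scope="session")
def ref_eye():
    return build_eye()


@pytest.fixture(scope="session")
def selfcons_map(ref_eye):
    """Body density exactly consistent with the RF surface at E2v = 2."""
    return make_selfconsistent_density(2.0, ref_eye, d0_deg=2.0,
                                       meridian_step_deg=10.0)


@pytest.fixture(scope="session")
def selfcons_field(selfcons_map, ref_eye):
    return build_displacement_field(selfcons_map, ref_eye, n_meridians=36)


@pytest.fixture(scope="session")
def synth_map():
    """Generic fovea-peaked, meridionally asymmetric synthetic density."""
    return synthetic_density()


@pytest.fixture(scope="session")
def synth_field(synth_map, ref_eye):
    return build_displacement_field(synth_map, ref_eye, n_meridians=72)


@pytest.fixture(scope="session")
def uniform_map():
    """Spatially uniform body density map (1000 cells/mm^2 out to 5 mm)."""
    from drasdo.density_maps import RetinalDensityMap
    mer = np.arange(0.0, 360.0, 30.0)
    ecc = np.linspace(0.0, 5.0, 51)
    dens = np.full((mer.size, ecc.size), 1000.0)
    return RetinalDensityMap(mer, ecc, dens, 11.459, "synthetic")
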