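import pytest

from ringlap.config_search import NAMED_CONFIGS
from ringlap.mesh_eval import MeshSpec, sweep

#: config-name -> CREConfig mapping used for all mesh sweeps, baseline last.
TRIPOLAR = {
    "optimal": NAMED_CONFIGS["OPTIMAL"],
    "liird": NAMED_CONFIGS["LIIRD"],
    "cird": NAMED_CONFIGS["CIRD"],
}

DIAMETERS = [0.5 * k for k in range(1, 11)]


@pytest.fixture(scope="session")
def mesh():
    return MeshSpec()


@pytest.fixture(scope="session")
def sweep_depth3(mesh):
    """Measures for all diameters at the reference dipole depth of 3 cm."""
    return sweep(TRIPOLAR, DIAMETERS, [3.0], mesh=mesh)


@pytest.fixture(scope="session")
def full_sweep(mesh):
    """Measures over the complete diameter x depth validation grid."""
    return sweep(TRIPOLAR, DIAMETERS, [float(d) for d in range(1, 11)], mesh=mesh)
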