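import numpy as np
import pytest

from letfield import materials
from letfield.geometry import GeometryPoint
from letfield.moments import FluenceSpectrum
from letfield.spectra import PhotonBeamModel


@pytest.fixture(scope="session")
def water():
    return materials.WATER


@pytest.fixture(scope="session")
def table():
    """Default water stopping-power table, Δ = 1 keV, 1 keV–6.5 MeV."""
    return materials.build_table(materials.default_energy_grid(), delta_kev=1.0)


@pytest.fixture(scope="session")
def beam():
    return PhotonBeamModel()


@pytest.fixture
def geom_in_field():
    return GeometryPoint(2.7, 1.35, 0.0)


@pytest.fixture
def geom_edge_plus_2():
    return GeometryPoint(2.7, 1.35, 3.35)


def monoenergetic_spectrum(e0_mev, half_width=1.001, **kwargs):
    """Single geometric-symmetric bin centred exactly on e0."""
    edges = np.array([e0_mev / half_width, e0_mev * half_width])
    kwargs.setdefault("track_end_fluence", 0.0)
    return FluenceSpectrum(bin_edges_mev=edges, fluence_density=np.array([1.0]), **kwargs)


def power_law_table(mids, values, delta_kev=1.0, e_lo=1e-3, e_hi=None):
    """Synthetic table whose log-log interpolation passes exactly through
    (mids[i], values[i]); restricted == unrestricted."""
    mids = np.asarray(mids, dtype=float)
    values = np.asarray(values, dtype=float)
    slope = np.log(values[-1] / values[0]) / np.log(mids[-1] / mids[0])
    e_hi = e_hi or mids[-1] * 4
    grid = np.unique(np.concatenate([[e_lo], mids, [e_hi]]))
    vals = values[0] * (grid / mids[0]) ** slope
    return materials.StoppingPowerTable(grid, vals, vals, delta_kev)
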