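import numpy as np
import pytest

from cncmap.bands import BandGrid, Spectrum, gaussian_resample, harmonized_grid, load_sensor_grid
from cncmap.rtm import simulate_sample
from cncmap.rtm.prospect import LeafParams
from cncmap.rtm.sail import CanopyParams, ViewGeometry


@pytest.fixture(scope="session")
def sensor_grid() -> BandGrid:
    return load_sensor_grid()


@pytest.fixture(scope="session")
def hgrid(sensor_grid) -> BandGrid:
    return harmonized_grid(sensor_grid)


@pytest.fixture(scope="session")
def reference_leaf() -> LeafParams:
    """A mid-season crop leaf used across tests."""
    return LeafParams(
        N_struct=1.5, C_ab=40.0, C_xc=8.0, C_anth=1.0, C_w=0.01, C_p=0.0015, CBC=0.005
    )


@pytest.fixture(scope="session")
def reference_canopy() -> CanopyParams:
    return CanopyParams(LAI=3.0, ALA=50.0, HotS=0.1, alpha_soil=0.6)


@pytest.fixture(scope="session")
def clean_sensor_spectrum(sensor_grid, reference_leaf, reference_canopy) -> Spectrum:
    """Artifact-free simulated canopy spectrum on the full sensor grid."""
    fine = Spectrum(
        BandGrid.fine(), simulate_sample(reference_leaf, reference_canopy, ViewGeometry())
    )
    return gaussian_resample(fine, sensor_grid)


@pytest.fixture(scope="session")
def small_database(hgrid):
    from cncmap.rtm import build_training_database

    return build_training_database(150, hgrid, seed=42)
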