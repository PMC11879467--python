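import numpy as np
import pytest

from beamkin.loc import BeamConditions, LOCParams
from beamkin.fixtures import study_constants
from beamkin.synth import study_conditions


@pytest.fixture(scope="session")
def fixtures_table():
    return study_constants()


@pytest.fixture(scope="session")
def study_beam_conditions():
    """Beam conditions of the study: 310 K, 0.65 eV lab FWHM, 165/34 amu."""
    return study_conditions(0)


@pytest.fixture
def toy_conditions():
    """Light-weight conditions (few modes) for fast convolution tests."""
    return BeamConditions(
        m_ion=100.0,
        m_neutral=20.0,
        t_ion=300.0,
        t_neutral=300.0,
        fwhm_lab=0.3,
        ion_frequencies=(300.0, 900.0, 1500.0),
        neutral_frequencies=(800.0,),
        ion_rotational_model="nonlinear",
        neutral_rotational_model="nonlinear",
    )


@pytest.fixture
def delta_conditions():
    """Degenerate conditions: no energy spread, (numerically) cold reactants."""
    return BeamConditions(
        m_ion=100.0,
        m_neutral=20.0,
        t_ion=1e-6,
        t_neutral=1e-6,
        fwhm_lab=0.0,
        ion_frequencies=(300.0, 900.0),
        neutral_frequencies=(800.0,),
    )


@pytest.fixture
def loc_params():
    return LOCParams(sigma0=2.0, e0=0.5, n=2.4)


@pytest.fixture
def energy_grid():
    return np.linspace(0.2, 3.0, 15)
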