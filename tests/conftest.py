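import numpy as np
import pytest

from flimfret.decay import IRFModel, MultiExpModel
from flimfret.synthetic import (MCHERRY, MNEONGREEN, make_decay,
                                make_fluorophore_spectra)

#: donor-only mean lifetime in cells (ns) and the tandem-construct
#: triexponential decomposition used throughout the recovery tests
DONOR_CELL_TAU = 3.02
M1_AMPLITUDES = (0.372, 0.464, 0.164)
M1_LIFETIMES = (3.0, 2.0, 0.6)


@pytest.fixture(scope="session")
def nm_grid():
    return np.arange(420.0, 721.0, 1.0)


@pytest.fixture(scope="session")
def mneongreen_spectra(nm_grid):
    return make_fluorophore_spectra(MNEONGREEN, nm_grid)


@pytest.fixture(scope="session")
def mcherry_spectra(nm_grid):
    return make_fluorophore_spectra(MCHERRY, nm_grid)


@pytest.fixture(scope="session")
def m1_triple():
    return MultiExpModel(np.array(M1_AMPLITUDES), np.array(M1_LIFETIMES))


@pytest.fixture(scope="session")
def gen_irf():
    """IRF used for data generation: 150 ps FWHM, centered 2 ns into the window."""
    return IRFModel(0.150, 2.0)


@pytest.fixture(scope="session")
def fit_irf():
    """IRF assumed by fits: width known, shift left free."""
    return IRFModel(0.150)


@pytest.fixture(scope="session")
def m1_histogram(m1_triple, gen_irf):
    """One seeded 1e6-count realization of the tandem triple at 20 MHz."""
    hist, truth = make_decay(m1_triple, gen_irf, 1e6, 1024, 50.0, seed=0)
    return hist, truth
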