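import numpy as np
import pytest

from mlcpen import MachineScene, SourceDistribution, TSTParams, leaf_end


@pytest.fixture(scope="session")
def scene():
    """Reference geometric model: tungsten leaves, 8 cm height at SCD 46 cm."""
    return MachineScene(sad=100.0, scd=46.0, fs=40.0, lh=8.0, rho=19.3,
                        mu_rho=0.05, sdd=33.9, dh=7.8)


@pytest.fixture(scope="session")
def src():
    """0.2 cm FWHM Gaussian focal spot."""
    return SourceDistribution(fwhms=(0.2,), weights=(1.0,))


@pytest.fixture(scope="session")
def tst():
    """Canonical calibrated TST parameters for the reference model."""
    return TSTParams(e=0.152, l=1.174)


@pytest.fixture(scope="session")
def positions():
    return np.linspace(-20.0, 20.0, 17)


@pytest.fixture(scope="session")
def circ_opt():
    """Mean-optimal circular arc of the reference model."""
    return leaf_end("circular", 8.0, R=16.213, d=-0.732)


@pytest.fixture(scope="session")
def bez_opt():
    return leaf_end("bezier", 8.0, control=[(-1.594, 1.077), (0.814, 0.748)])


@pytest.fixture(scope="session")
def ell_opt():
    return leaf_end("elliptical", 8.0, b=0.728)
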