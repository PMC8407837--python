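import numpy as np
import pytest

import lutloc


@pytest.fixture(scope="session")
def calib():
    """Symmetric astigmatic calibration (sigma_x(z) == sigma_y(-z), focus 0)."""
    return lutloc.default_calibration()


@pytest.fixture(scope="session")
def small_table(calib):
    """Coarse table kept small for fast unit tests."""
    spec = lutloc.LookupTableSpec(window=9, dxy=0.1, rxy=1.0, dz=50.0, rz=400.0)
    return lutloc.build_table(spec, calib)


@pytest.fixture(scope="session")
def default_table(calib):
    """Full-resolution table (dxy 0.1 px, dz 25 nm) shared across tests."""
    return lutloc.build_table(lutloc.LookupTableSpec(), calib)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
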