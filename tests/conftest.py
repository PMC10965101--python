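import numpy as np
import pytest

from kcsdkit import (BasisConfig, ElectrodeSetup, build_kernels,
                     default_basis, default_estimation_space,
                     place_basis_regular)


@pytest.fixture(scope="session")
def probe_1d():
    """8-contact laminar probe on [0, 1] with a 5-source Gaussian basis."""
    setup = ElectrodeSetup(np.linspace(0.0, 1.0, 8)[:, None], sigma=1.0)
    space = default_estimation_space(setup, 41)
    centers = place_basis_regular(setup.bounding_box(), [5])
    basis = BasisConfig("gaussian", R=0.15, h=0.1, centers=centers)
    model = build_kernels(setup, basis, space)
    return {"setup": setup, "space": space, "basis": basis, "model": model}


@pytest.fixture(scope="session")
def grid_3x3():
    """3×3 unit grid of electrodes with the default oversampled basis."""
    pos = np.array([[i, j] for i in range(3) for j in range(3)], dtype=float)
    setup = ElectrodeSetup(pos, sigma=1.0)
    space = default_estimation_space(setup, 15)
    basis = default_basis(setup, R=1.0, h=0.5)
    model = build_kernels(setup, basis, space)
    return {"setup": setup, "space": space, "basis": basis, "model": model}
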