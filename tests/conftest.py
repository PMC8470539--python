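import numpy as np
import pytest

import pottsnet as pn
from pottsnet.simulators import generate_potts_ensemble
from pottsnet.trainer import TrainerOptions, fit


@pytest.fixture(scope="session")
def lattice_2x3():
    return pn.build_lattice([2, 3], periodic=False)


@pytest.fixture(scope="session")
def true_params_2x3():
    """Ground-truth 2-state model used by the recovery experiments."""
    return pn.PottsParameters(h=np.array([1.0, -1.0]),
                              J=[np.array([[-4.0, 2.0], [2.0, -4.0]])])


@pytest.fixture(scope="session")
def recovery_fit(lattice_2x3, true_params_2x3):
    """500 exact draws from the known model, fitted once and reused."""
    ens = generate_potts_ensemble(true_params_2x3, lattice_2x3, 500, seed=7,
                                  method="exact")
    result = fit(ens, lattice_2x3,
                 TrainerOptions(seed=3, n_kept=4000, burn_in=300, stride=5,
                                max_iter=300))
    return ens, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
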