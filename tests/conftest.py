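import numpy as np
import pytest

import ionscale as isc
from ionscale.surrogate import SurrogateConfig, generate_surrogate

# Printed reference tables (4 significant figures) used across the suite.
TABLE2 = {
    "K+": (0.183, 6.32, 4.86e3, 1.65e7),
    "Na+": (0.128, 10.8, 2.21e4, 8.88e7),
    "Ca2+": (0.053, 6.18, 1.87e4, 9.23e7),
    "Cl-": (0.177, 6.98, 6.56e3, 2.97e7),
}
TABLE3 = {
    "K+": (768.7, 152.5, 3.393e3, 7.094e4),
    "Na+": (2.044e3, 166.1, 4.020e3, 1.717e5),
    "Ca2+": (3.026e3, 190.2, 4.933e3, 1.874e5),
    "Cl-": (940.0, 189.7, 4.524e3, 1.061e5),
}
# eigenvalues (real root, Re/Im of the conjugate pair) and MSD time shifts
TABLE4 = {
    "K+": (-127.0, -12.75, 27.58, 3.08e-2, -9.39e-3),
    "Na+": (-140.1, -12.99, 47.47, 6.15e-3, -2.35e-2),
    "Ca2+": (-163.1, -13.58, 57.84, 1.47e-3, -2.48e-2),
    "Cl-": (-162.9, -13.41, 30.25, 2.50e-2, -1.13e-2),
}
# published N=3 fictitious-particle coefficients for K+
ALPHA_K_N3 = np.array(
    [
        [5.64e2, 73.8, 3.42e3, 80.9],
        [1.26e2, 21.3, 7.27e2, 3.43e-1],
        [72.1, 2.02e2, 3.26e-1, 1.22e2],
    ]
)

IONS = list(TABLE2)


@pytest.fixture(scope="session")
def kplus():
    return isc.get_ion("K+")


@pytest.fixture(scope="session")
def kplus_params(kplus):
    return kplus[1]


@pytest.fixture(scope="session")
def kplus_stats(kplus):
    return kplus[0]


@pytest.fixture(scope="session")
def kplus_surrogate(kplus_params):
    """One long exact-sampled K+ surrogate trajectory shared by estimator tests."""
    cfg = SurrogateConfig(reference=kplus_params, n_steps=1_000_000, seed=1)
    return generate_surrogate(cfg)


@pytest.fixture(scope="session")
def kplus_em_trajectory(kplus_params):
    """One long Euler-Maruyama K+ run (stationary start) for jerk statistics."""
    rng = np.random.default_rng(5)
    V0, U0, Z0 = isc.sample_stationary(kplus_params, rng=rng)
    init = isc.CGState(0.0, np.zeros(3), V0, U0, Z0)
    return isc.simulate_cg(kplus_params, init, dt=1e-3, n_steps=1_000_000, seed=6)
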