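import numpy as np
import pytest

import otk

#: Stokes drag of the default bead (6*pi*eta*a), frozen from direct arithmetic.
GAMMA_BEAD = 6.0 * np.pi * 8.9e-4 * 2.4e-6  # 4.0263e-8 N s/m
#: closed-form corner frequency kx / (2*pi*gamma)
FC_BEAD = 1.0e-5 / (2.0 * np.pi * GAMMA_BEAD)  # 39.53 Hz


@pytest.fixture(scope="session")
def trap():
    return otk.TrapConfig()


@pytest.fixture(scope="session")
def no_binding():
    return otk.BindingSchedule()


@pytest.fixture(scope="session")
def binding_schedule():
    return otk.BindingSchedule(kon=1e6, koff=0.0, ligand_conc=5e-9,
                               layer_thickness=7e-9)


@pytest.fixture(scope="session")
def short_sim():
    """40 s constant-drag record: enough for ~35 segments after a 5 s discard."""
    return otk.SimConfig(duration=40.0, seed=11)


@pytest.fixture(scope="session")
def short_qpd(trap, no_binding, short_sim):
    traj = otk.simulate_trajectory(trap, no_binding, short_sim)
    return otk.render_qpd(traj, short_sim, no_binding)


@pytest.fixture(scope="session")
def fast_spectral_cfg():
    return otk.SpectralConfig(discard_initial=5.0)


@pytest.fixture(scope="session")
def short_gamma_traj(short_qpd, fast_spectral_cfg):
    return otk.gamma_trajectory(short_qpd, fast_spectral_cfg)
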