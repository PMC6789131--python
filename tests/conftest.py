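import numpy as np
import pytest

import heatflow as hf


@pytest.fixture(scope="session")
def topo10():
    """Ten-residue 3_10-helix topology with Aib-like 13-atom residues."""
    return hf.build_topology(10, "310")


@pytest.fixture(scope="session")
def constant_rate_traj(topo10):
    """Noiseless trajectory from the constant-rate exchange model
    (k_BB = 1.5, k_HB = 0.5, k_s = 0.05 ps^-1, T_B = 300 K)."""
    model = hf.KineticModel.constant_rates(topo10, 1.5, 0.5, 0.05, 300.0)
    return hf.simulate_master_equation(
        model, hf.HeaterProtocol(), n_members=1, seed=11, total_time=25.0, noise_scale=0.0
    )[0]


@pytest.fixture(scope="session")
def free_segment(constant_rate_traj):
    """Free-relaxation segment (after heater release at 1 ps)."""
    return constant_rate_traj.window(1.0)


@pytest.fixture(scope="session")
def fitted_rates(free_segment, topo10):
    return hf.fit_rates(free_segment, topo10)


def make_equilibrium_trajectory(n_res=4, n_frames=6, t_b=300.0, atoms=13):
    dof = np.full(n_res, 3 * atoms)
    energies = np.tile(0.5 * dof[:, None] * hf.K_B * t_b, (1, n_frames))
    return hf.EnergyTrajectory(
        times=0.1 * np.arange(n_frames),
        energies=energies,
        dof=dof,
        bath_temperature=t_b,
    )
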