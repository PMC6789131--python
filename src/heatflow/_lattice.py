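"""Numba kernels for the 1-D nonlinear (FPU-beta) lattice integrator.

Units: displacements nm, velocities nm/ps, masses u, spring constants eV/nm^2
(harmonic) and eV/nm^4 (quartic). Forces in eV/nm are converted to
accelerations in nm/ps^2 through U_NM2_PS2_PER_EV.
"""

import numpy as np
from numba import njit

from .constants import U_NM2_PS2_PER_EV


@njit
def seed_rng(seed):
    np.random.seed(seed)


@njit
def forces(u, k_harm, beta, out):
    n = u.shape[0]
    for i in range(n):
        out[i] = 0.0
    for b in range(n - 1):
        s = u[b + 1] - u[b]
        f = k_harm * s + beta * s * s * s  # bond tension, eV/nm
        out[b] += f
        out[b + 1] -= f


@njit
def total_energy(u, v, mass, k_harm, beta):
    """Total energy in eV: kinetic + bond potential."""
    e = 0.0
    for i in range(u.shape[0]):
        e += 0.5 * mass * v[i] * v[i] / U_NM2_PS2_PER_EV
    for b in range(u.shape[0] - 1):
        s = u[b + 1] - u[b]
        e += 0.5 * k_harm * s * s + 0.25 * beta * s * s * s * s
    return e


@njit
def run_segment(u, v, n_steps, dt, mass, k_harm, beta, friction, sigma_v, thermostat):
    """Advance n_steps with velocity Verlet (BAOAB when thermostatted).

    sigma_v[i] is the Maxwell-Boltzmann velocity scale of site i (nm/ps);
    thermostat is a 0/1 mask per site. With friction <= 0 or an all-zero
    mask this reduces to plain velocity Verlet (NVE).
    """
    n = u.shape[0]
    f = np.empty(n)
    forces(u, k_harm, beta, f)
    acc_conv = U_NM2_PS2_PER_EV / mass
    use_thermo = friction > 0.0
    c1 = np.exp(-friction * dt) if use_thermo else 1.0
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    for _ in range(n_steps):
        for i in range(n):
            v[i] += 0.5 * dt * f[i] * acc_conv
        if use_thermo:
            for i in range(n):
                u[i] += 0.5 * dt * v[i]
            for i in range(n):
                if thermostat[i] == 1:
                    v[i] = c1 * v[i] + c2 * sigma_v[i] * np.random.normal()
            for i in range(n):
                u[i] += 0.5 * dt * v[i]
        else:
            for i in range(n):
                u[i] += dt * v[i]
        forces(u, k_harm, beta, f)
        for i in range(n):
            v[i] += 0.5 * dt * f[i] * acc_conv
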