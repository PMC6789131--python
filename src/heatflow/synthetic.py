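"""Synthetic data generators for pipeline validation by parameter recovery.

Two generators are provided:

* :func:`simulate_master_equation` integrates the residue-level exchange
  model forward in time (RK4) under the transient-heating protocol — one
  residue pinned at ``T_B + ΔT`` for a heating window, then free relaxation —
  and emits ensembles with configurable finite-ensemble observation noise.
  Rates are constant or activated (Arrhenius ``k = Ω exp(−ΔG/k_B T)`` with T
  the bath temperature, or optionally the instantaneous pair-mean kinetic
  temperature), so that every downstream estimator can be checked against
  known ground truth.

* :func:`simulate_lattice` is a desk-scale surrogate for all-atom
  non-equilibrium MD: a 1-D FPU-β chain (harmonic + quartic bonds) with a
  Langevin-thermostatted heater segment, integrated by velocity Verlet, whose
  per-site frames aggregate into pseudo-residues for end-to-end tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _lattice
from .constants import K_B, U_NM2_PS2_PER_EV
from .master_equation import ContactTopology, build_topology
from .trajectory_io import AtomFrame, EnergyTrajectory, write_results

__all__ = [
    "KineticModel",
    "HeaterProtocol",
    "LatticeChain",
    "LatticeRun",
    "simulate_master_equation",
    "simulate_lattice",
    "simulate_lattice_arrays",
    "lattice_sound_speed",
    "make_fixture_suite",
]


@dataclass
class KineticModel:
    """Ground-truth exchange model: topology plus per-channel rate laws.

    ``omega`` and ``barrier`` map channel names ("backbone", "hbond") to the
    Arrhenius attempt frequency Ω (ps⁻¹) and barrier ΔG (eV); the channel
    rate is ``k = Ω exp(−ΔG/k_B T)``. With ``temperature_dependent=False``
    (default) T is the bath temperature, so rates are constant in time and
    Arrhenius across bath conditions; with ``temperature_dependent=True`` T
    is the instantaneous pair-mean kinetic temperature (local activation).
    """

    topology: ContactTopology
    omega: dict[str, float]
    barrier: dict[str, float]
    k_solvent_true: float
    bath_temperature: float
    temperature_dependent: bool = False

    def __post_init__(self) -> None:
        for ch in ("backbone", "hbond"):
            if self.omega.get(ch, 0.0) < 0:
                raise ValueError(f"omega[{ch!r}] must be >= 0")
            if self.barrier.get(ch, 0.0) < 0:
                raise ValueError(f"barrier[{ch!r}] must be >= 0")
        if self.k_solvent_true < 0:
            raise ValueError("k_solvent_true must be >= 0")

    @classmethod
    def constant_rates(
        cls,
        topology: ContactTopology,
        k_backbone: float,
        k_hbond: float,
        k_solvent: float,
        bath_temperature: float,
    ) -> "KineticModel":
        return cls(
            topology=topology,
            omega={"backbone": k_backbone, "hbond": k_hbond},
            barrier={"backbone": 0.0, "hbond": 0.0},
            k_solvent_true=k_solvent,
            bath_temperature=bath_temperature,
            temperature_dependent=False,
        )

    @classmethod
    def arrhenius(
        cls,
        topology: ContactTopology,
        omega: float,
        delta_g: float,
        k_solvent: float,
        bath_temperature: float,
        *,
        local_temperature: bool = False,
    ) -> "KineticModel":
        """Activated rates ``k = Ω exp(−ΔG/k_B T)`` on both channels.

        By default T is the bath temperature (rates constant within a
        trajectory, Arrhenius across baths); ``local_temperature=True``
        evaluates T at the instantaneous pair mean instead.
        """
        return cls(
            topology=topology,
            omega={"backbone": omega, "hbond": omega},
            barrier={"backbone": delta_g, "hbond": delta_g},
            k_solvent_true=k_solvent,
            bath_temperature=bath_temperature,
            temperature_dependent=local_temperature,
        )

    @property
    def solvent_energy(self) -> np.ndarray:
        """E_s,j = (f_j/2) k_B T_B per residue, eV."""
        return 0.5 * self.topology.dof * K_B * self.bath_temperature

    def rate(self, channel: str, temperature: float | None = None) -> float:
        """Channel rate ``Ω exp(−ΔG/k_B T)`` (T defaults to the bath)."""
        t = self.bath_temperature if temperature is None else temperature
        dg = self.barrier.get(channel, 0.0)
        if dg == 0.0:
            return self.omega[channel]
        return self.omega[channel] * math.exp(-dg / (K_B * max(t, 1e-6)))


@dataclass
class HeaterProtocol:
    """Transient heating protocol: one residue held at T_B + ΔT, then released."""

    heater_index: int = 1
    delta_T: float = 670.0
    duration: float = 1.0
    record_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be positive")


def _pair_arrays(topo: ContactTopology):
    pairs = [(i - 1, j - 1, "backbone") for i, j in topo.backbone_pairs] + [
        (i - 1, j - 1, "hbond") for i, j in topo.hbond_pairs
    ]
    pi = np.array([p[0] for p in pairs], dtype=int)
    pj = np.array([p[1] for p in pairs], dtype=int)
    is_bb = np.array([p[2] == "backbone" for p in pairs])
    return pi, pj, is_bb


def simulate_master_equation(
    model: KineticModel,
    protocol: HeaterProtocol,
    n_members: int = 1,
    seed: int = 0,
    *,
    total_time: float = 25.0,
    noise_scale: float = 0.3,
    internal_step: float = 1e-3,
) -> list[EnergyTrajectory]:
    """Forward-simulate the exchange model under the heating protocol.

    Deterministic RK4 at ``internal_step`` (ps), recorded every
    ``protocol.record_interval``. During the heating window the heater
    residue's energy is pinned to ``(f/2) k_B (T_B + ΔT)`` (a Dirichlet
    condition — the deterministic analogue of thermostatting one residue);
    afterwards all residues evolve freely. Ensemble members share the
    deterministic solution and differ by independent Gaussian observation
    noise on each recorded energy with standard deviation
    ``noise_scale · √(f_j/2) · k_B · T_j`` (the equipartition energy
    fluctuation scale at the local temperature, reduced by ``noise_scale`` to
    emulate block-averaged sampling). Member streams derive from
    ``(seed, bath temperature, member index)`` so ensembles are
    reproducible, order-independent, and uncorrelated across conditions.
    """
    topo = model.topology
    n = topo.n_residues
    if not 1 <= protocol.heater_index <= n:
        raise ValueError("heater index outside the chain")
    f = topo.dof.astype(float)
    e_s = model.solvent_energy
    r_surf = topo.surface_factor
    pi, pj, is_bb = _pair_arrays(topo)
    frat = f[pi] / f[pj]
    k_const = np.where(
        is_bb, model.rate("backbone"), model.rate("hbond") if topo.hbond_pairs else 0.0
    )
    omega = np.where(is_bb, model.omega["backbone"], model.omega.get("hbond", 0.0))
    dg = np.where(is_bb, model.barrier["backbone"], model.barrier.get("hbond", 0.0))
    h = protocol.heater_index - 1
    e_pin = 0.5 * f[h] * K_B * (model.bath_temperature + protocol.delta_T)
    ks = model.k_solvent_true

    def rhs(e: np.ndarray, pinned: bool) -> np.ndarray:
        if model.temperature_dependent:
            t = 2.0 * e / (f * K_B)
            t_loc = 0.5 * (t[pi] + t[pj])
            k = omega * np.exp(-dg / (K_B * np.maximum(t_loc, 1e-6)))
        else:
            k = k_const
        flux = k * (e[pi] - frat * e[pj])
        de = np.zeros_like(e)
        np.subtract.at(de, pi, flux)
        np.add.at(de, pj, flux)
        de -= r_surf * ks * (e - e_s)
        if pinned:
            de[h] = 0.0
        return de

    steps_per_record = max(1, round(protocol.record_interval / internal_step))
    dt = protocol.record_interval / steps_per_record
    n_records = int(round(total_time / protocol.record_interval)) + 1

    e = 0.5 * f * K_B * model.bath_temperature
    e[h] = e_pin
    times = np.empty(n_records)
    energies = np.empty((n, n_records))
    times[0] = 0.0
    energies[:, 0] = e
    t = 0.0
    emax_guard = 1e3 * max(e_pin, float(np.max(e)))
    for rec in range(1, n_records):
        for _ in range(steps_per_record):
            pinned = t < protocol.duration - 1e-12
            k1 = rhs(e, pinned)
            k2 = rhs(e + 0.5 * dt * k1, pinned)
            k3 = rhs(e + 0.5 * dt * k2, pinned)
            k4 = rhs(e + dt * k3, pinned)
            e = e + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if t < protocol.duration - 1e-12:
                e[h] = e_pin
        if not np.all(np.isfinite(e)) or np.max(e) > emax_guard:
            raise FloatingPointError(
                f"integration unstable at t={t:.3f} ps (max E = {np.max(e):.3g} eV); "
                "reduce the internal step"
            )
        times[rec] = rec * protocol.record_interval
        energies[:, rec] = e

    sigma = noise_scale * np.sqrt(f[:, None] / 2.0) * K_B * (
        2.0 * energies / (f[:, None] * K_B)
    )
    members = []
    # stream key includes the bath so ensembles at different conditions draw
    # independent noise even under one master seed
    bath_key = int(round(model.bath_temperature * 1000)) % (2**31 - 1)
    for m in range(n_members):
        if noise_scale > 0:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), bath_key, m]))
            obs = energies + sigma * rng.standard_normal(energies.shape)
            obs = np.maximum(obs, 0.0)
        else:
            obs = energies.copy()
        members.append(
            EnergyTrajectory(
                times=times.copy(),
                energies=obs,
                dof=topo.dof.copy(),
                bath_temperature=model.bath_temperature,
                heater_index=protocol.heater_index,
                ensemble_id=f"{seed}:{m}",
            )
        )
    return members


# ---------------------------------------------------------------------------
# FPU-beta lattice surrogate
# ---------------------------------------------------------------------------


@dataclass
class LatticeChain:
    """1-D nonlinear lattice standing in for all-atom NEMD.

    Nearest-neighbour bonds carry a harmonic (eV/nm²) plus quartic
    (FPU-β, eV/nm⁴) potential. A heater segment (1-based inclusive site
    range) is Langevin-thermostatted at ``heater_temperature`` for
    ``heater_duration`` ps while the remaining sites are thermostatted at
    ``bath_temperature``; thereafter the chain is microcanonical. Groups of
    ``sites_per_residue`` consecutive sites form pseudo-residues when frames
    are aggregated.
    """

    n_sites: int = 64
    mass: float = 12.0
    spacing: float = 0.15
    harmonic_k: float = 10.0
    quartic_beta: float = 200.0
    sites_per_residue: int = 8
    heater_segment: tuple[int, int] = (1, 8)
    heater_temperature: float = 970.0
    bath_temperature: float = 300.0
    heater_duration: float = 1.0
    bath_friction: float = 10.0
    timestep: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.harmonic_k <= 0:
            raise ValueError("mass and harmonic_k must be positive")
        if self.quartic_beta < 0:
            raise ValueError("quartic_beta must be >= 0")
        omega_max = 2.0 * math.sqrt(self.harmonic_k * U_NM2_PS2_PER_EV / self.mass)
        if self.timestep >= 2.0 / omega_max:
            raise ValueError(
                f"timestep {self.timestep} ps exceeds the stability bound "
                f"{2.0 / omega_max:.2e} ps"
            )
        lo, hi = self.heater_segment
        if not (1 <= lo <= hi <= self.n_sites):
            raise ValueError("heater_segment out of range")


def lattice_sound_speed(chain: LatticeChain) -> float:
    """Harmonic sound speed c = a·√(k/m) (nm/ps), the maximal group velocity."""
    return chain.spacing * math.sqrt(chain.harmonic_k * U_NM2_PS2_PER_EV / chain.mass)


@dataclass
class LatticeRun:
    """Raw lattice output: per-record displacements/velocities and energy."""

    chain: LatticeChain
    times: np.ndarray
    displacements: np.ndarray  # (records, sites), nm
    velocities: np.ndarray  # (records, sites), nm/ps
    total_energy: np.ndarray  # (records,), eV

    def site_kinetic_energy(self) -> np.ndarray:
        """(records, sites) kinetic energies in eV."""
        return 0.5 * self.chain.mass * self.velocities**2 / U_NM2_PS2_PER_EV

    def frames(self) -> list[list[AtomFrame]]:
        """Per-site frames with pseudo-residue grouping (1-D velocities are
        embedded as the x component)."""
        g = self.chain.sites_per_residue
        out = []
        for n, t in enumerate(self.times):
            frame = [
                AtomFrame(
                    time=float(t),
                    atom_id=i + 1,
                    residue_index=i // g + 1,
                    mass=self.chain.mass,
                    velocity=np.array([self.velocities[n, i], 0.0, 0.0]),
                )
                for i in range(self.chain.n_sites)
            ]
            out.append(frame)
        return out


def simulate_lattice_arrays(
    chain: LatticeChain,
    total_time: float,
    *,
    record_interval: float = 0.1,
    thermostat: bool = True,
    initial_velocities: np.ndarray | None = None,
) -> LatticeRun:
    """Integrate the chain and return raw arrays (see :class:`LatticeRun`).

    With ``thermostat=False`` (or zero friction) the run is microcanonical
    throughout — used for conservation and pulse-propagation checks.
    """
    n = chain.n_sites
    u = np.zeros(n)
    v = (
        np.zeros(n)
        if initial_velocities is None
        else np.asarray(initial_velocities, dtype=float).copy()
    )
    if v.shape != (n,):
        raise ValueError("initial_velocities must have one entry per site")
    _lattice.seed_rng(chain.seed % (2**31 - 1))

    target = np.full(n, chain.bath_temperature)
    lo, hi = chain.heater_segment
    target[lo - 1 : hi] = chain.heater_temperature
    sigma_v = np.sqrt(K_B * target * U_NM2_PS2_PER_EV / chain.mass)
    mask_on = np.ones(n, dtype=np.int64)
    mask_off = np.zeros(n, dtype=np.int64)

    steps_per_record = max(1, round(record_interval / chain.timestep))
    dt = record_interval / steps_per_record
    n_records = int(round(total_time / record_interval)) + 1
    times = np.arange(n_records) * record_interval
    us = np.empty((n_records, n))
    vs = np.empty((n_records, n))
    energy = np.empty(n_records)
    us[0], vs[0] = u, v
    energy[0] = _lattice.total_energy(u, v, chain.mass, chain.harmonic_k, chain.quartic_beta)
    for rec in range(1, n_records):
        t_now = times[rec - 1]
        heating = thermostat and chain.bath_friction > 0 and t_now < chain.heater_duration - 1e-12
        _lattice.run_segment(
            u,
            v,
            steps_per_record,
            dt,
            chain.mass,
            chain.harmonic_k,
            chain.quartic_beta,
            chain.bath_friction if heating else 0.0,
            sigma_v,
            mask_on if heating else mask_off,
        )
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise FloatingPointError(f"lattice integration blew up at t={times[rec]:.3f} ps")
        us[rec], vs[rec] = u, v
        energy[rec] = _lattice.total_energy(
            u, v, chain.mass, chain.harmonic_k, chain.quartic_beta
        )
    return LatticeRun(chain=chain, times=times, displacements=us, velocities=vs, total_energy=energy)


def simulate_lattice(
    chain: LatticeChain,
    total_time: float,
    *,
    record_interval: float = 0.1,
    thermostat: bool = True,
    initial_velocities: np.ndarray | None = None,
) -> list[list[AtomFrame]]:
    """Integrate the chain and emit per-site :class:`AtomFrame` sequences."""
    run = simulate_lattice_arrays(
        chain,
        total_time,
        record_interval=record_interval,
        thermostat=thermostat,
        initial_velocities=initial_velocities,
    )
    return run.frames()


# ---------------------------------------------------------------------------
# Standard fixture battery
# ---------------------------------------------------------------------------

FIXTURE_BATHS = (230.0, 250.0, 270.0, 290.0, 310.0, 330.0)


def make_fixture_suite(
    seed: int,
    out_dir,
    *,
    n_members: int = 2,
    n_residues: int = 10,
    total_time: float = 5.0,
) -> dict:
    """Write the standard synthetic battery and return its manifest.

    (i) noiseless constant-rate ensembles (k_BB = 1.5, k_HB = 0.5,
    k_s = 0.05 ps⁻¹) at six bath temperatures 230–330 K in 20 K steps,
    10 residues, 3₁₀ topology, heater at residue 1; (ii) Arrhenius ensembles
    with ΔG = 0.05 eV, Ω = 5 ps⁻¹ at the same baths; (iii) one small lattice
    run. Same seed ⇒ byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo = build_topology(n_residues, "310")
    protocol = HeaterProtocol(heater_index=1)
    manifest: dict = {"seed": int(seed), "entries": []}

    for kind in ("constant", "arrhenius"):
        for t_b in FIXTURE_BATHS:
            if kind == "constant":
                model = KineticModel.constant_rates(topo, 1.5, 0.5, 0.05, t_b)
                noise = 0.0
                params = {"k_backbone": 1.5, "k_hbond": 0.5, "k_solvent": 0.05}
            else:
                model = KineticModel.arrhenius(topo, 5.0, 0.05, 0.05, t_b)
                noise = 0.3
                params = {"omega": 5.0, "delta_g": 0.05, "k_solvent": 0.05}
            members = simulate_master_equation(
                model,
                protocol,
                n_members=n_members,
                seed=seed,
                total_time=total_time,
                noise_scale=noise,
            )
            e_dep = float(members[0].energies[:, 0].sum() - 0.5 * topo.dof.sum() * K_B * t_b)
            for m, traj in enumerate(members):
                name = f"{kind}_tb{int(t_b)}_m{m}.dat"
                write_results(traj, out / name)
                manifest["entries"].append(
                    {
                        "file": name,
                        "kind": kind,
                        "bath_temperature": t_b,
                        "member": m,
                        "heater_index": protocol.heater_index,
                        "deposited_energy_ev": e_dep,
                        "noise_scale": noise,
                        **params,
                    }
                )

    chain = LatticeChain(seed=seed)
    run = simulate_lattice_arrays(chain, 2.0, record_interval=0.1)
    lattice_file = out / "lattice_run.tsv"
    with open(lattice_file, "w") as fh:
        for n, t in enumerate(run.times):
            fh.write(f"t {t:.6f} natoms {chain.n_sites}\n")
            for i in range(chain.n_sites):
                fh.write(
                    f"{i + 1} {i // chain.sites_per_residue + 1} "
                    f"{chain.mass:.17g} {run.velocities[n, i]:.17g} 0 0\n"
                )
    manifest["entries"].append(
        {
            "file": "lattice_run.tsv",
            "kind": "lattice",
            "n_sites": chain.n_sites,
            "sites_per_residue": chain.sites_per_residue,
            "harmonic_k": chain.harmonic_k,
            "quartic_beta": chain.quartic_beta,
            "spacing": chain.spacing,
            "mass": chain.mass,
            "sound_speed_nm_ps": lattice_sound_speed(chain),
            "seed": int(seed),
        }
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
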