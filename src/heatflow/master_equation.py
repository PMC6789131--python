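"""Constrained master-equation rate inversion.

The kinetic model for transient energy flow treats each residue's kinetic
energy ``E_j(t)`` as a node in an exchange network::

    dE_j/dt = Σ_i k_pair(i,j) [E_i − (f_i/f_j) E_j]  −  R_j k_s (E_j − E_s,j)

where the sum runs over residues coupled to ``j`` (backbone neighbours and
hydrogen-bond partners), ``f_j`` are per-residue degrees of freedom,
``E_s,j = (f_j/2) k_B T_B`` is the bath-equilibrium energy, ``k_s`` the
solvent coupling rate, and ``R_j`` a geometric surface factor (termini couple
more strongly). The exchange term ``E_i − (f_i/f_j) E_j`` vanishes exactly at
equipartition (``E_j ∝ f_j``), which makes the equilibrium state stationary
and fixes the detailed-balance relation ``k_ji = (f_i/f_j) k_ij``.

Per analysis time bin the unknown vector ``k = (k_{1,2}, …, k_{N−1,N}, k_HB)``
is recovered by non-negative least squares::

    k(t_n) = argmin_{k ≥ 0} ½ ‖G(t_n) k − d(t_n)‖²

with rows of ``G`` indexed by residues and columns by unknown rates, and
``d_j = [E_j(t_n) − E_j(t_{n−1})]/Δt + R_j k_s [E_j − E_s,j]`` the residue
energy change corrected for solvent exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import nnls

from .constants import K_B
from .trajectory_io import EnergyTrajectory

__all__ = [
    "ContactTopology",
    "RateFitSeries",
    "FluxGradientRecord",
    "build_topology",
    "detailed_balance_reverse",
    "solvent_rate",
    "SolventRate",
    "assemble_system",
    "fit_rates",
    "compute_fluxes",
    "effective_gradient",
]


@dataclass
class ContactTopology:
    """Backbone + hydrogen-bond coupling graph with per-residue metadata.

    ``backbone_pairs`` is always the simple path (1,2)…(n−1,n);
    ``hbond_pairs`` are non-adjacent (j, j+k) contacts sharing one rate
    ``k_HB``. ``surface_factor`` R_j scales the solvent coupling of residue j
    (termini default to a larger value). All residue indices are 1-based.
    """

    n_residues: int
    backbone_pairs: list[tuple[int, int]]
    hbond_pairs: list[tuple[int, int]]
    surface_factor: np.ndarray
    dof: np.ndarray

    def __post_init__(self) -> None:
        n = self.n_residues
        if n < 2:
            raise ValueError("need at least 2 residues")
        expected = [(j, j + 1) for j in range(1, n)]
        if list(self.backbone_pairs) != expected:
            raise ValueError("backbone pairs must form the simple path 1..n")
        seen = set()
        for i, j in self.hbond_pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"hbond pair ({i},{j}) out of range for n={n}")
            if j - i < 2:
                raise ValueError(f"hbond pair ({i},{j}) is backbone-adjacent")
            if (i, j) in seen:
                raise ValueError(f"duplicate hbond pair ({i},{j})")
            seen.add((i, j))
        self.surface_factor = np.asarray(self.surface_factor, dtype=float)
        self.dof = np.asarray(self.dof, dtype=int)
        if self.surface_factor.shape != (n,) or np.any(self.surface_factor <= 0):
            raise ValueError("surface_factor must be positive, one per residue")
        if self.dof.shape != (n,) or np.any(self.dof < 3):
            raise ValueError("dof must be >= 3, one per residue")

    @property
    def n_unknowns(self) -> int:
        """Backbone rates plus one shared hydrogen-bond rate (if any)."""
        return self.n_residues - 1 + (1 if self.hbond_pairs else 0)

    @property
    def atoms_per_residue(self) -> np.ndarray:
        return self.dof // 3


def build_topology(
    n: int,
    helix: Literal["310", "alpha", "custom"] = "310",
    hbond_pairs: Sequence[tuple[int, int]] | None = None,
    *,
    atoms_per_residue: int | Sequence[int] = 13,
    terminal_surface_factor: float = 1.5,
    dof: Sequence[int] | None = None,
) -> ContactTopology:
    """Construct the coupling topology of an ideal helix.

    ``helix="310"`` adds hydrogen bonds (j, j+3); ``"alpha"`` adds (j, j+4);
    ``"custom"`` takes an explicit pair list. Terminal residues get a larger
    solvent surface factor (default 1.5; interior residues 1.0). The default
    atom count per residue (13) matches an Aib residue.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    if helix == "310":
        pairs = [(j, j + 3) for j in range(1, n - 2)]
    elif helix == "alpha":
        pairs = [(j, j + 4) for j in range(1, n - 3)]
    elif helix == "custom":
        pairs = list(hbond_pairs or [])
    else:
        raise ValueError(f"unknown helix type {helix!r}")
    if dof is None:
        atoms = np.broadcast_to(np.asarray(atoms_per_residue, dtype=int), (n,))
        dof_arr = 3 * atoms
    else:
        dof_arr = np.asarray(dof, dtype=int)
    surface = np.ones(n)
    surface[0] = surface[-1] = terminal_surface_factor
    return ContactTopology(
        n_residues=n,
        backbone_pairs=[(j, j + 1) for j in range(1, n)],
        hbond_pairs=pairs,
        surface_factor=surface,
        dof=dof_arr,
    )


def read_topology_file(path, n: int, **kwargs) -> ContactTopology:
    """Read a plain-text pair list (``i j channel`` per line) into a topology.

    Backbone lines are checked against the implied path; ``hbond`` lines make
    up the custom pair list.
    """
    hb = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j, channel = line.split()
        if channel == "hbond":
            hb.append((int(i), int(j)))
        elif channel != "backbone":
            raise ValueError(f"unknown channel {channel!r} in {path}")
    return build_topology(n, "custom", hb, **kwargs)


def detailed_balance_reverse(k_ij: float, f_i: float, f_j: float) -> float:
    """Reverse rate ``k_ji = (f_i/f_j) k_ij`` for the transfer i → j.

    This is the relation under which the equipartition state ``E_j ∝ f_j`` is
    exactly stationary: the pair flux ``k_ij E_i − k_ji E_j`` vanishes when
    ``E_i/f_i = E_j/f_j``.
    """
    if f_i <= 0 or f_j <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (f_i / f_j) * k_ij


class SolventRate(NamedTuple):
    value: float
    clamped: bool
    n_omitted: int


def solvent_rate(
    traj: EnergyTrajectory,
    n: int,
    *,
    topology: ContactTopology | None = None,
    method: Literal["balance", "printed"] = "balance",
    guard: float = 1e-6,
    clamp: bool = True,
) -> SolventRate:
    """Estimate the solvent coupling rate ``k_s(t_n)`` (ps⁻¹) for bin ``n``.

    ``method="balance"`` (default) closes the total energy budget: exchange
    between residues conserves energy, so the total drift is attributable to
    the solvent alone,

        k_s = −[Σ_j ΔE_j/Δt] / [Σ_j R_j (Ē_j − E_s,j)]

    with Ē the bin-midpoint energy. This is exact on noiseless model data.

    ``method="printed"`` evaluates the per-residue ratio sum
    ``Σ_j ΔE_j / (E_j(t_n) − E_s,j)`` divided by the bin width, with
    sign flipped so relaxation toward the bath yields a positive rate; terms
    with |denominator| below ``guard`` (eV) are omitted.

    Negative results are clamped to 0 (flagged) since k_s must be
    non-negative.
    """
    if n < 1 or n >= traj.n_frames:
        raise IndexError(f"bin index {n} needs a predecessor frame")
    dt = traj.times[n] - traj.times[n - 1]
    e_now = traj.energies[:, n]
    e_prev = traj.energies[:, n - 1]
    e_s = traj.solvent_energy
    r = np.ones(traj.n_residues) if topology is None else topology.surface_factor

    n_omitted = 0
    if method == "balance":
        denom_terms = r * (0.5 * (e_now + e_prev) - e_s)
        denom = float(np.sum(denom_terms))
        if abs(denom) < guard:
            return SolventRate(0.0, False, traj.n_residues)
        value = -float(np.sum(e_now - e_prev)) / (denom * dt)
    elif method == "printed":
        denom = e_now - e_s
        keep = np.abs(denom) >= guard
        n_omitted = int(np.sum(~keep))
        if not np.any(keep):
            return SolventRate(0.0, False, n_omitted)
        value = -float(np.sum((e_now - e_prev)[keep] / denom[keep])) / dt
    else:
        raise ValueError(f"unknown solvent_rate method {method!r}")

    clamped = False
    if clamp and value < 0:
        value, clamped = 0.0, True
    return SolventRate(value, clamped, n_omitted)


def _bin_energies(traj: EnergyTrajectory, n: int, energy_eval: str) -> np.ndarray:
    if energy_eval == "mid":
        return 0.5 * (traj.energies[:, n] + traj.energies[:, n - 1])
    if energy_eval == "right":
        return traj.energies[:, n]
    raise ValueError(f"unknown energy_eval {energy_eval!r}")


def assemble_system(
    traj: EnergyTrajectory,
    topo: ContactTopology,
    n: int,
    k_s: float,
    *,
    energy_eval: Literal["mid", "right"] = "mid",
    strict_paper_g: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the linear system ``G k ≈ d`` for time bin ``n``.

    Rows are residues; columns are the unknown rates
    ``(k_{1,2}, …, k_{N−1,N}[, k_HB])``. A backbone column for pair (i, i+1)
    carries ``−x`` in row i and ``+x`` in row i+1 with
    ``x = E_i − (f_i/f_{i+1}) E_{i+1}``; the shared hydrogen-bond column sums
    the analogous terms over all hbond pairs. With ``strict_paper_g`` the
    dof ratio is dropped (``x = E_i − E_j``), which coincides with the scaled
    form whenever the paired residues have equal dof.

    ``d_j = ΔE_j/Δt + R_j k_s (E_j − E_s,j)`` isolates the intra-peptide
    exchange. Energies enter at the bin midpoint by default, consistent with
    the centered finite difference.
    """
    if n < 1 or n >= traj.n_frames:
        raise IndexError(f"bin index {n} out of range")
    dt = traj.times[n] - traj.times[n - 1]
    e = _bin_energies(traj, n, energy_eval)
    f = topo.dof.astype(float)

    def exchange(i: int, j: int) -> float:
        # 0-based indices; flux i -> j up to the rate constant
        if strict_paper_g:
            return e[i] - e[j]
        return e[i] - (f[i] / f[j]) * e[j]

    n_res = topo.n_residues
    g = np.zeros((n_res, topo.n_unknowns))
    for col, (i1, j1) in enumerate(topo.backbone_pairs):
        i, j = i1 - 1, j1 - 1
        x = exchange(i, j)
        g[i, col] = -x
        g[j, col] = +x
    if topo.hbond_pairs:
        for i1, j1 in topo.hbond_pairs:
            i, j = i1 - 1, j1 - 1
            x = exchange(i, j)
            g[i, -1] += -x
            g[j, -1] += +x

    d = (traj.energies[:, n] - traj.energies[:, n - 1]) / dt
    d += topo.surface_factor * k_s * (e - traj.solvent_energy)
    return g, d


@dataclass
class RateFitSeries:
    """Fitted rate constants per analysis time bin.

    ``k_backbone`` has shape (n_residues − 1, n_bins); ``k_hbond`` and
    ``k_solvent`` are scalars per bin. ``degenerate`` marks bins where the
    system carried no exchange signal (G ≈ 0) and rates default to zero.
    """

    bin_times: np.ndarray
    k_backbone: np.ndarray
    k_hbond: np.ndarray
    k_solvent: np.ndarray
    residual_norm: np.ndarray
    feasible: np.ndarray
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.k_backbone = np.asarray(self.k_backbone, dtype=float)
        self.k_hbond = np.asarray(self.k_hbond, dtype=float)
        self.k_solvent = np.asarray(self.k_solvent, dtype=float)
        self.residual_norm = np.asarray(self.residual_norm, dtype=float)
        self.feasible = np.asarray(self.feasible, dtype=bool)
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.feasible)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if np.any(self.k_backbone < 0) or np.any(self.k_hbond < 0) or np.any(self.k_solvent < 0):
            raise ValueError("rates must be non-negative")
        if np.any(self.residual_norm < 0):
            raise ValueError("residual norms must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.k_backbone.shape[0] + 1

    @property
    def n_bins(self) -> int:
        return self.bin_times.size

    def rate_for_pair(self, pair: tuple[int, int], topo: ContactTopology) -> np.ndarray:
        """Time series of the fitted rate governing a given coupled pair."""
        pair = tuple(sorted(pair))
        for col, bb in enumerate(topo.backbone_pairs):
            if bb == pair:
                return self.k_backbone[col]
        if pair in [tuple(sorted(p)) for p in topo.hbond_pairs]:
            return self.k_hbond
        raise KeyError(f"pair {pair} not in topology")


def fit_rates(
    traj: EnergyTrajectory,
    topo: ContactTopology,
    *,
    window: int = 3,
    energy_eval: Literal["mid", "right"] = "mid",
    solvent_method: Literal["balance", "printed"] = "balance",
    strict_paper_g: bool = False,
    degenerate_tol: float = 1e-11,
) -> RateFitSeries:
    """Fit per-bin rate constants by non-negative least squares.

    For each pair of consecutive frames the solvent rate is estimated, the
    linear system assembled, and ``min_{k≥0} ½‖Gk − d‖²`` solved with an
    active-set NNLS solver (deterministic; no randomness).

    Because pairwise exchange conserves energy, every column of a single
    bin's ``G`` sums to zero, so a system with a shared hydrogen-bond rate
    (N unknowns, N residue rows) has rank at most N − 1 and the per-bin
    minimizer is not unique. ``fit_rates`` therefore stacks a centered
    sliding ``window`` of consecutive bins per solve (default 3; rates are
    treated as locally constant over the window, the model's own
    coarse-graining premise), which restores full rank whenever the energy
    configuration evolves between bins. ``window=1`` gives the strict
    single-bin behaviour. Edge bins use clipped (asymmetric) windows.

    Bins whose stacked ``G`` carries no signal relative to the trajectory's
    energy scale are flagged degenerate and return zero rates.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to fit rates")
    if window < 1:
        raise ValueError("window must be >= 1")
    n_bins = traj.n_frames - 1
    n_bb = topo.n_residues - 1
    has_hb = bool(topo.hbond_pairs)

    bin_times = 0.5 * (traj.times[1:] + traj.times[:-1])
    k_bb = np.zeros((n_bb, n_bins))
    k_hb = np.zeros(n_bins)
    k_s = np.zeros(n_bins)
    res = np.zeros(n_bins)
    feas = np.ones(n_bins, dtype=bool)
    degen = np.zeros(n_bins, dtype=bool)

    # Pre-assemble one system per bin, then solve on stacked windows.
    systems = []
    for b in range(n_bins):
        n = b + 1
        ks = solvent_rate(traj, n, topology=topo, method=solvent_method)
        k_s[b] = ks.value
        systems.append(
            assemble_system(
                traj, topo, n, ks.value, energy_eval=energy_eval, strict_paper_g=strict_paper_g
            )
        )

    scale = max(float(np.max(np.abs(traj.energies))), 1e-300)
    half = (window - 1) // 2
    for b in range(n_bins):
        lo = max(0, min(b - half, n_bins - window))
        hi = min(n_bins, lo + window)
        g = np.vstack([systems[q][0] for q in range(lo, hi)])
        d = np.concatenate([systems[q][1] for q in range(lo, hi)])
        if np.max(np.abs(g)) <= degenerate_tol * scale:
            degen[b] = True
            res[b] = float(np.linalg.norm(systems[b][1]))
            continue
        sol, rnorm = nnls_solve(g, d)
        k_bb[:, b] = sol[:n_bb]
        if has_hb:
            k_hb[b] = sol[-1]
        res[b] = rnorm
    return RateFitSeries(
        bin_times=bin_times,
        k_backbone=k_bb,
        k_hbond=k_hb,
        k_solvent=k_s,
        residual_norm=res,
        feasible=feas,
        degenerate=degen,
    )


def nnls_solve(g: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve ``min_{k>=0} ||G k - d||`` (active-set NNLS; deterministic).

    This is the constrained solver used by :func:`fit_rates`; exposed so that
    oracle cross-checks exercise the same code path.
    """
    return nnls(np.asarray(g, float), np.asarray(d, float))


def effective_gradient(e_i: float, e_j: float, f_i: float, f_j: float, n_atoms: int) -> float:
    """Effective temperature gradient Δ_ij T_eff (K) across a coupled pair.

    ``Δ_ij T_eff = 2 [E_i − (f_i/f_j) E_j] / (3 N k_B)`` with ``N`` the atom
    count of the residue the flux is incident on (the accepting residue).
    Zero exactly at equipartition ``E_i/f_i = E_j/f_j``.
    """
    if n_atoms < 1:
        raise ValueError("atom count must be >= 1")
    if f_i <= 0 or f_j <= 0:
        raise ValueError("degrees of freedom must be positive")
    return 2.0 * (e_i - (f_i / f_j) * e_j) / (3.0 * n_atoms * K_B)


@dataclass(frozen=True)
class FluxGradientRecord:
    """Pairwise flux with its effective gradient, one record per pair/bin.

    Sign convention: positive flux corresponds to flow away from the heater.
    ``pair`` is ordered (near-heater, far-from-heater); ``mean_elevation`` is
    the pair-averaged kinetic temperature elevation over the bath.
    """

    bin_time: float
    pair: tuple[int, int]
    flux: float
    gradient: float
    mean_elevation: float
    bath_temperature: float
    channel: str
    rate: float = 0.0


def compute_fluxes(
    traj: EnergyTrajectory,
    topo: ContactTopology,
    rates: RateFitSeries,
    *,
    energy_eval: Literal["mid", "right"] = "mid",
) -> list[FluxGradientRecord]:
    """Pairwise heat fluxes ``J = k [E_near − (f_near/f_far) E_far]`` per bin.

    Pairs are oriented away from the heater residue; if both members are
    equidistant from the heater, both directed records are emitted. The
    effective gradient uses the accepting (far) residue's atom count.
    """
    if rates.n_bins != traj.n_frames - 1:
        raise ValueError("rate series and trajectory bins do not match")
    f = topo.dof.astype(float)
    atoms = topo.atoms_per_residue
    h = traj.heater_index
    t_b = traj.bath_temperature
    temps = traj.kinetic_temperature()
    records: list[FluxGradientRecord] = []

    pair_list: list[tuple[tuple[int, int], str, int | None]] = [
        (p, "backbone", col) for col, p in enumerate(topo.backbone_pairs)
    ] + [(p, "hbond", None) for p in topo.hbond_pairs]

    for b in range(rates.n_bins):
        n = b + 1
        e = _bin_energies(traj, n, energy_eval)
        t_mid = 0.5 * (temps[:, n] + temps[:, n - 1]) if energy_eval == "mid" else temps[:, n]
        for (i1, j1), channel, col in pair_list:
            k = rates.k_backbone[col, b] if channel == "backbone" else rates.k_hbond[b]
            di, dj = abs(i1 - h), abs(j1 - h)
            orientations = []
            if di <= dj:
                orientations.append((i1, j1))
            if dj <= di:
                orientations.append((j1, i1))
            for a1, b1 in orientations:
                i, j = a1 - 1, b1 - 1
                flux = k * (e[i] - (f[i] / f[j]) * e[j])
                grad = effective_gradient(e[i], e[j], f[i], f[j], atoms[j])
                elev = 0.5 * (t_mid[i] + t_mid[j]) - t_b
                records.append(
                    FluxGradientRecord(
                        bin_time=float(rates.bin_times[b]),
                        pair=(a1, b1),
                        flux=float(flux),
                        gradient=float(grad),
                        mean_elevation=float(elev),
                        bath_temperature=t_b,
                        channel=channel,
                        rate=float(k),
                    )
                )
    return records
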