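"""Containers and plain-text I/O for per-residue energy trajectories.

The package works on per-residue kinetic energies ``E_j(t)`` (eV) on a common
time grid. Raw per-atom velocity dumps can be aggregated into residue
energies; equivalently, tables of per-residue kinetic *temperatures* are
converted through equipartition, ``E_j = (f_j/2) k_B T_j`` with ``f_j = 3 N_j``
degrees of freedom for a residue of ``N_j`` atoms.

All on-disk formats are delimited text. Floating-point values are written
with 17 significant digits so that read(write(x)) round-trips bitwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import EV_PER_U_NM2_PS2, K_B

__all__ = [
    "AtomFrame",
    "EnergyTrajectory",
    "TrajectoryError",
    "read_energy_table",
    "read_atom_dump",
    "aggregate_atoms",
    "write_results",
    "read_results",
    "write_ensemble_h5",
    "read_ensemble_h5",
]

_FLOAT_FMT = "%.17g"


class TrajectoryError(ValueError):
    """Raised for malformed trajectory data, with row-level context."""


@dataclass(frozen=True)
class AtomFrame:
    """One atom's record in one frame of a per-atom dump.

    Velocities are in nm/ps, masses in u, times in ps. ``residue_index`` is
    1-based.
    """

    time: float
    atom_id: int
    residue_index: int
    mass: float
    velocity: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise TrajectoryError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.mass <= 0:
            raise TrajectoryError(f"atom {self.atom_id}: mass must be positive, got {self.mass}")
        v = np.asarray(self.velocity, dtype=float)
        if v.shape != (3,):
            raise TrajectoryError(f"atom {self.atom_id}: velocity must be a 3-vector")
        object.__setattr__(self, "velocity", v)

    @property
    def kinetic_energy(self) -> float:
        """Kinetic energy ½ m |v|² in eV."""
        return 0.5 * self.mass * float(self.velocity @ self.velocity) * EV_PER_U_NM2_PS2


@dataclass
class EnergyTrajectory:
    """Per-residue kinetic energies on a strictly increasing time grid.

    Attributes
    ----------
    times : (n_frames,) array, ps
    energies : (n_residues, n_frames) array, eV
    dof : (n_residues,) int array
        Degrees of freedom per residue, ``f_j = 3 N_j`` unless overridden.
    bath_temperature : float, K
    heater_index : int
        1-based index of the transiently heated residue.
    ensemble_id : str
    """

    times: np.ndarray
    energies: np.ndarray
    dof: np.ndarray
    bath_temperature: float
    heater_index: int = 1
    ensemble_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.dof = np.asarray(self.dof, dtype=int)
        if self.times.ndim != 1:
            raise TrajectoryError("times must be 1-D")
        if self.energies.ndim != 2 or self.energies.shape[1] != self.times.size:
            raise TrajectoryError(
                f"energies must be (n_residues, {self.times.size}), got {self.energies.shape}"
            )
        if self.energies.shape[0] < 2:
            raise TrajectoryError("need at least 2 residues")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times) > 0))
            raise TrajectoryError(f"times not strictly increasing at row {bad + 1}")
        if np.any(self.energies < 0):
            j, n = np.argwhere(self.energies < 0)[0]
            raise TrajectoryError(f"negative energy for residue {j + 1} at frame {n}")
        if self.dof.shape != (self.energies.shape[0],):
            raise TrajectoryError("dof must have one entry per residue")
        if np.any(self.dof < 3):
            raise TrajectoryError("each residue needs dof >= 3")
        if not 1 <= self.heater_index <= self.energies.shape[0]:
            raise TrajectoryError(f"heater_index {self.heater_index} out of range")

    @property
    def n_residues(self) -> int:
        return self.energies.shape[0]

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def solvent_energy(self) -> np.ndarray:
        """Bath-equilibrium energies E_s,j = (f_j/2) k_B T_B, eV."""
        return 0.5 * self.dof * K_B * self.bath_temperature

    def kinetic_temperature(self) -> np.ndarray:
        """Kinetic temperatures T_j(t) = 2 E_j / (f_j k_B), K."""
        return 2.0 * self.energies / (self.dof[:, None] * K_B)

    def elevation(self) -> np.ndarray:
        """Temperature elevation over the bath, ΔT_B,j(t), K."""
        return self.kinetic_temperature() - self.bath_temperature

    def window(self, t_start: float = -np.inf, t_stop: float = np.inf) -> "EnergyTrajectory":
        """Restrict to frames with t_start <= t <= t_stop (e.g. the
        free-relaxation segment after heater release)."""
        mask = (self.times >= t_start - 1e-12) & (self.times <= t_stop + 1e-12)
        if int(mask.sum()) < 2:
            raise TrajectoryError("window leaves fewer than 2 frames")
        return EnergyTrajectory(
            times=self.times[mask],
            energies=self.energies[:, mask],
            dof=self.dof.copy(),
            bath_temperature=self.bath_temperature,
            heater_index=self.heater_index,
            ensemble_id=self.ensemble_id,
        )


def temperature_to_energy(temperature, dof):
    """Equipartition conversion T → E = (f/2) k_B T (eV)."""
    return 0.5 * np.asarray(dof, dtype=float) * K_B * np.asarray(temperature, dtype=float)


def energy_to_temperature(energy, dof):
    """Equipartition conversion E → T = 2E/(f k_B) (K)."""
    return 2.0 * np.asarray(energy, dtype=float) / (np.asarray(dof, dtype=float) * K_B)


def _tokenize_table(path) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.replace(",", " ").split())
    return rows


def read_energy_table(
    path,
    *,
    dof: Sequence[int],
    bath_temperature: float,
    heater_index: int = 1,
    temperature_mode: bool = False,
    ensemble_id: str = "",
) -> EnergyTrajectory:
    """Read a delimited per-residue table into an :class:`EnergyTrajectory`.

    The file holds one header line then one row per frame: first column time
    (ps), remaining columns per-residue energy (eV), or kinetic temperature
    (K) when ``temperature_mode`` is set (converted via ``E = (f/2) k_B T``).
    Whitespace and comma delimiters are accepted; ``#`` lines are comments.
    """
    rows = _tokenize_table(path)
    if len(rows) < 2:
        raise TrajectoryError(f"{path}: expected a header line and at least one data row")
    header, data = rows[0], rows[1:]
    ncol = len(header)
    if ncol < 3:
        raise TrajectoryError(f"{path}: need a time column plus >= 2 residue columns")
    dof = np.asarray(dof, dtype=int)
    if dof.size != ncol - 1:
        raise TrajectoryError(
            f"{path}: table has {ncol - 1} residue columns but {dof.size} dof entries given"
        )
    values = np.empty((len(data), ncol))
    for i, row in enumerate(data):
        if len(row) != ncol:
            raise TrajectoryError(f"{path}: row {i + 2} has {len(row)} columns, expected {ncol}")
        try:
            values[i] = [float(x) for x in row]
        except ValueError as exc:
            raise TrajectoryError(f"{path}: row {i + 2}: {exc}") from None
    times = values[:, 0]
    series = values[:, 1:].T
    if temperature_mode:
        series = temperature_to_energy(series, dof[:, None])
    return EnergyTrajectory(
        times=times,
        energies=series,
        dof=dof,
        bath_temperature=bath_temperature,
        heater_index=heater_index,
        ensemble_id=ensemble_id,
    )


def read_atom_dump(path) -> list[list[AtomFrame]]:
    """Read a fixed-column per-atom dump into per-frame atom lists.

    Format: frame blocks headed by ``t <time_ps> natoms <n>`` followed by
    ``n`` rows ``id res mass vx vy vz``.
    """
    frames: list[list[AtomFrame]] = []
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 4 or head[0] != "t" or head[2] != "natoms":
            raise TrajectoryError(f"{path}: malformed frame header at line {i + 1}: {lines[i]!r}")
        t, natoms = float(head[1]), int(head[3])
        block = []
        for row in lines[i + 1 : i + 1 + natoms]:
            f = row.split()
            if len(f) != 6:
                raise TrajectoryError(f"{path}: malformed atom row {row!r}")
            block.append(
                AtomFrame(
                    time=t,
                    atom_id=int(f[0]),
                    residue_index=int(f[1]),
                    mass=float(f[2]),
                    velocity=np.array([float(f[3]), float(f[4]), float(f[5])]),
                )
            )
        if len(block) != natoms:
            raise TrajectoryError(f"{path}: frame at t={t} truncated")
        frames.append(block)
        i += 1 + natoms
    return frames


def aggregate_atoms(
    frames: Sequence[Sequence[AtomFrame]],
    *,
    bath_temperature: float,
    heater_index: int = 1,
    dof_override: Sequence[int] | None = None,
    ensemble_id: str = "",
) -> EnergyTrajectory:
    """Aggregate per-atom frames into per-residue kinetic energies.

    ``E_j(t) = Σ_{atoms ∈ j} ½ m |v|²`` in eV; per-residue degrees of freedom
    are recorded as ``f_j = 3 N_j`` (constraint corrections, if any, are the
    caller's responsibility via ``dof_override``). The kinetic temperature is
    then recoverable as ``T_j = 2 E_j / (f_j k_B)``.
    """
    if not frames or not frames[0]:
        raise TrajectoryError("no frames to aggregate")
    mapping: dict[int, int] = {}
    for atom in frames[0]:
        if atom.atom_id in mapping and mapping[atom.atom_id] != atom.residue_index:
            raise TrajectoryError(f"atom {atom.atom_id} appears in two residues")
        mapping[atom.atom_id] = atom.residue_index
    residues = sorted({a.residue_index for a in frames[0]})
    if residues != list(range(1, len(residues) + 1)):
        raise TrajectoryError(f"residue indices must be contiguous from 1, got {residues}")
    counts = np.zeros(len(residues), dtype=int)
    for a in frames[0]:
        counts[a.residue_index - 1] += 1
    if np.any(counts == 0):
        raise TrajectoryError("residue with zero atoms")

    times = np.empty(len(frames))
    energies = np.zeros((len(residues), len(frames)))
    ref_ids = set(mapping)
    for n, frame in enumerate(frames):
        ids = {a.atom_id for a in frame}
        if ids != ref_ids:
            raise TrajectoryError(f"frame {n}: atom set differs from frame 0")
        times[n] = frame[0].time
        for a in frame:
            if mapping[a.atom_id] != a.residue_index:
                raise TrajectoryError(f"atom {a.atom_id} appears in two residues")
            energies[a.residue_index - 1, n] += a.kinetic_energy
    dof = 3 * counts if dof_override is None else np.asarray(dof_override, dtype=int)
    return EnergyTrajectory(
        times=times,
        energies=energies,
        dof=dof,
        bath_temperature=bath_temperature,
        heater_index=heater_index,
        ensemble_id=ensemble_id,
    )


# ---------------------------------------------------------------------------
# Generic result writing: tagged delimited text, bitwise round-trip stable.
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return _FLOAT_FMT % float(x)


def _write_matrix(buf: io.StringIO, header: Sequence[str], columns: Sequence[np.ndarray]) -> None:
    buf.write("\t".join(header) + "\n")
    for row in zip(*columns):
        buf.write("\t".join(_fmt(x) for x in row) + "\n")


def write_results(obj, path) -> None:
    """Write any of the package's record types to a tagged text file.

    Dispatches on type; files open with ``# heatflow <TypeName>`` and
    round-trip through :func:`read_results` to full stored precision.
    """
    from . import coarse_grain, master_equation  # local import to avoid cycles

    buf = io.StringIO()
    if isinstance(obj, EnergyTrajectory):
        buf.write("# heatflow EnergyTrajectory\n")
        buf.write(f"# bath_temperature {_fmt(obj.bath_temperature)}\n")
        buf.write(f"# heater_index {obj.heater_index}\n")
        buf.write(f"# ensemble_id {obj.ensemble_id}\n")
        buf.write("# dof " + " ".join(str(d) for d in obj.dof) + "\n")
        header = ["time_ps"] + [f"E_res{j + 1}" for j in range(obj.n_residues)]
        _write_matrix(buf, header, [obj.times, *obj.energies])
    elif isinstance(obj, master_equation.RateFitSeries):
        buf.write("# heatflow RateFitSeries\n")
        buf.write(f"# n_residues {obj.n_residues}\n")
        header = (
            ["bin_time_ps"]
            + [f"k_{j + 1}_{j + 2}" for j in range(obj.n_residues - 1)]
            + ["k_hbond", "k_solvent", "residual_norm", "feasible", "degenerate"]
        )
        _write_matrix(
            buf,
            header,
            [
                obj.bin_times,
                *obj.k_backbone,
                obj.k_hbond,
                obj.k_solvent,
                obj.residual_norm,
                obj.feasible,
                obj.degenerate,
            ],
        )
    elif isinstance(obj, coarse_grain.TransportProfile):
        buf.write("# heatflow TransportProfile\n")
        buf.write(f"# n_members {obj.n_members}\n")
        buf.write(f"# subensemble {obj.subensemble_label}\n")
        buf.write(f"# heater_index {obj.heater_index if obj.heater_index else 0}\n")
        nres = obj.elevation.shape[0]
        header = (
            ["time_ps"]
            + [f"dT_res{j + 1}" for j in range(nres)]
            + [f"sem_res{j + 1}" for j in range(nres)]
        )
        _write_matrix(buf, header, [obj.times, *obj.elevation, *obj.sem])
    elif _is_flux_sequence(obj):
        buf.write("# heatflow FluxGradientRecords\n")
        header = [
            "bin_time_ps",
            "i",
            "j",
            "channel",
            "flux_ev_ps",
            "gradient_K",
            "mean_elevation_K",
            "bath_temperature_K",
            "rate_ps",
        ]
        buf.write("\t".join(header) + "\n")
        for r in obj:
            buf.write(
                "\t".join(
                    [
                        _fmt(r.bin_time),
                        str(r.pair[0]),
                        str(r.pair[1]),
                        r.channel,
                        _fmt(r.flux),
                        _fmt(r.gradient),
                        _fmt(r.mean_elevation),
                        _fmt(r.bath_temperature),
                        _fmt(r.rate),
                    ]
                )
                + "\n"
            )
    else:
        raise TypeError(f"write_results: unsupported type {type(obj).__name__}")
    Path(path).write_text(buf.getvalue())


def _is_flux_sequence(obj) -> bool:
    from .master_equation import FluxGradientRecord

    return isinstance(obj, (list, tuple)) and all(
        isinstance(r, FluxGradientRecord) for r in obj
    )


def read_results(path):
    """Read back a file written by :func:`write_results`."""
    from .coarse_grain import TransportProfile
    from .master_equation import FluxGradientRecord, RateFitSeries

    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# heatflow "):
        raise TrajectoryError(f"{path}: not a heatflow results file")
    kind = text[0].split()[2]
    meta: dict[str, str] = {}
    body_start = 1
    for i, line in enumerate(text[1:], start=1):
        if line.startswith("# "):
            key, _, val = line[2:].partition(" ")
            meta[key] = val
        else:
            body_start = i
            break
    body = [ln.split("\t") for ln in text[body_start:] if ln.strip()]
    header, rows = body[0], body[1:]

    if kind == "EnergyTrajectory":
        arr = np.array([[float(x) for x in row] for row in rows])
        return EnergyTrajectory(
            times=arr[:, 0],
            energies=arr[:, 1:].T,
            dof=np.array([int(x) for x in meta["dof"].split()]),
            bath_temperature=float(meta["bath_temperature"]),
            heater_index=int(meta["heater_index"]),
            ensemble_id=meta.get("ensemble_id", ""),
        )
    if kind == "RateFitSeries":
        nres = int(meta["n_residues"])
        arr = np.array([[float(x) for x in row] for row in rows])
        if arr.size == 0:
            arr = arr.reshape(0, len(header))
        return RateFitSeries(
            bin_times=arr[:, 0],
            k_backbone=arr[:, 1:nres].T,
            k_hbond=arr[:, nres],
            k_solvent=arr[:, nres + 1],
            residual_norm=arr[:, nres + 2],
            feasible=arr[:, nres + 3].astype(bool),
            degenerate=arr[:, nres + 4].astype(bool),
        )
    if kind == "TransportProfile":
        arr = np.array([[float(x) for x in row] for row in rows])
        nres = (arr.shape[1] - 1) // 2
        heater = int(meta.get("heater_index", "0")) or None
        return TransportProfile(
            times=arr[:, 0],
            elevation=arr[:, 1 : 1 + nres].T,
            sem=arr[:, 1 + nres :].T,
            n_members=int(meta["n_members"]),
            subensemble_label=meta.get("subensemble", ""),
            heater_index=heater,
        )
    if kind == "FluxGradientRecords":
        out = []
        for row in rows:
            out.append(
                FluxGradientRecord(
                    bin_time=float(row[0]),
                    pair=(int(row[1]), int(row[2])),
                    channel=row[3],
                    flux=float(row[4]),
                    gradient=float(row[5]),
                    mean_elevation=float(row[6]),
                    bath_temperature=float(row[7]),
                    rate=float(row[8]),
                )
            )
        return out
    raise TrajectoryError(f"{path}: unknown record type {kind!r}")


# ---------------------------------------------------------------------------
# Single-file hierarchical container for trajectory ensembles.
# ---------------------------------------------------------------------------


def write_ensemble_h5(trajectories: Iterable[EnergyTrajectory], path) -> None:
    """Write an ensemble of trajectories to one HDF5 file (one group each)."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, traj in enumerate(trajectories):
            g = f.create_group(f"member_{i:05d}")
            g.create_dataset("times", data=traj.times)
            g.create_dataset("energies", data=traj.energies)
            g.create_dataset("dof", data=traj.dof)
            g.attrs["bath_temperature"] = traj.bath_temperature
            g.attrs["heater_index"] = traj.heater_index
            g.attrs["ensemble_id"] = traj.ensemble_id


def read_ensemble_h5(path) -> list[EnergyTrajectory]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                EnergyTrajectory(
                    times=g["times"][()],
                    energies=g["energies"][()],
                    dof=g["dof"][()],
                    bath_temperature=float(g.attrs["bath_temperature"]),
                    heater_index=int(g.attrs["heater_index"]),
                    ensemble_id=str(g.attrs["ensemble_id"]),
                )
            )
    return out
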