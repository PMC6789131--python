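"""Gradient-binned flux statistics, transport regimes, and barrier extraction.

Pairwise flux records are block-averaged in uniform bins of the effective
temperature gradient Δ_ij T_eff (default 1.0 K). Linear fits of flux versus
gradient inside a regime yield an effective per-link conductivity κ_eff
(the slope, eV K⁻¹ ps⁻¹) and diffusivity D_eff = slope · (Δx)² / C_link,
with C_link a per-link heat capacity. The flux-axis intercept is the
ballistic (zero-gradient) offset. Comparing low- and high-bath-temperature
flux curves through the Arrhenius relation
``J_H/J_L = exp(−ΔF/k_B T_H + ΔF/k_B T_L)`` yields effective free-energy
barriers ΔF. A separate, coarser diffusivity estimate inverts the
peak-arrival model ``t_max = d²/D`` on temperature-elevation profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .coarse_grain import TransportProfile
from .constants import K_B
from .master_equation import FluxGradientRecord

__all__ = [
    "GradientBinnedStats",
    "RegimeFit",
    "BarrierProfile",
    "DEFAULT_CLASSES",
    "bin_by_gradient",
    "fit_linear_regime",
    "segment_regimes",
    "barrier_from_ratio",
    "barrier_profile",
    "tmax_diffusivity",
]

#: Bath-temperature partition used throughout: low 230–270 K, high 290–330 K.
DEFAULT_CLASSES: dict[str, tuple[float, float]] = {
    "low": (230.0, 270.0),
    "high": (290.0, 330.0),
}

#: Default per-link heat capacity (eV/K): (3/2) N k_B for an N=13-atom residue.
DEFAULT_HEAT_CAPACITY = 1.5 * 13 * K_B


@dataclass
class GradientBinnedStats:
    """Flux/rate statistics block-averaged in uniform Δ_ij T_eff bins."""

    bin_edges: np.ndarray
    mean_flux: np.ndarray
    sem_flux: np.ndarray
    mean_rate: np.ndarray
    sem_rate: np.ndarray
    counts: np.ndarray
    mean_elevation: np.ndarray
    mean_temperature: np.ndarray
    mean_gradient: np.ndarray
    temperature_class: str
    min_count: int = 10

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        widths = np.diff(self.bin_edges)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin edges must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def reliable(self) -> np.ndarray:
        return self.counts >= self.min_count

    @property
    def width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return np.nan
    return float(values.std(ddof=1) / math.sqrt(values.size))


def bin_by_gradient(
    records: Sequence[FluxGradientRecord],
    width: float = 1.0,
    classes: Mapping[str, tuple[float, float]] | None = None,
    *,
    channel: str | None = "backbone",
    min_count: int = 10,
) -> dict[str, GradientBinnedStats]:
    """Block-average flux records in uniform gradient bins, per bath class.

    ``classes`` maps class names to inclusive bath-temperature ranges
    (default low 230–270 K / high 290–330 K; records outside every range are
    dropped). Bins are half-open ``[a, a+width)``. Bins with fewer than
    ``min_count`` members are flagged unreliable; the sem is defined only
    where a bin holds at least two records.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not records:
        raise ValueError("empty record set")
    if classes is None:
        classes = DEFAULT_CLASSES
    if channel is not None:
        records = [r for r in records if r.channel == channel]
        if not records:
            raise ValueError(f"no records on channel {channel!r}")

    grads = np.array([r.gradient for r in records])
    lo_edge = math.floor(grads.min() / width) * width
    hi_edge = math.ceil(grads.max() / width) * width
    if hi_edge <= lo_edge:
        hi_edge = lo_edge + width
    edges = lo_edge + width * np.arange(round((hi_edge - lo_edge) / width) + 1)
    n_bins = edges.size - 1

    out: dict[str, GradientBinnedStats] = {}
    baths = np.array([r.bath_temperature for r in records])
    flux = np.array([r.flux for r in records])
    rate = np.array([r.rate for r in records])
    elev = np.array([r.mean_elevation for r in records])
    idx_all = np.floor((grads - lo_edge) / width).astype(int)
    idx_all = np.clip(idx_all, 0, n_bins - 1)

    for name, (t_lo, t_hi) in classes.items():
        mask = (baths >= t_lo) & (baths <= t_hi)
        counts = np.zeros(n_bins, dtype=int)
        stats = {
            "mean_flux": np.full(n_bins, np.nan),
            "sem_flux": np.full(n_bins, np.nan),
            "mean_rate": np.full(n_bins, np.nan),
            "sem_rate": np.full(n_bins, np.nan),
            "mean_elevation": np.full(n_bins, np.nan),
            "mean_temperature": np.full(n_bins, np.nan),
            "mean_gradient": np.full(n_bins, np.nan),
        }
        idx = idx_all[mask]
        for b in range(n_bins):
            sel = idx == b
            counts[b] = int(np.sum(sel))
            if counts[b] == 0:
                continue
            stats["mean_flux"][b] = flux[mask][sel].mean()
            stats["sem_flux"][b] = _sem(flux[mask][sel])
            stats["mean_rate"][b] = rate[mask][sel].mean()
            stats["sem_rate"][b] = _sem(rate[mask][sel])
            stats["mean_elevation"][b] = elev[mask][sel].mean()
            stats["mean_temperature"][b] = (baths[mask][sel] + elev[mask][sel]).mean()
            stats["mean_gradient"][b] = grads[mask][sel].mean()
        out[name] = GradientBinnedStats(
            bin_edges=edges.copy(),
            counts=counts,
            temperature_class=name,
            min_count=min_count,
            **stats,
        )
    return out


@dataclass
class RegimeFit:
    """Linear transport fit over one gradient regime.

    ``kappa_eff`` is the fitted flux-vs-gradient slope (eV K⁻¹ ps⁻¹, per
    link); ``D_eff = slope · Δx² / C_link`` (nm² ps⁻¹); ``intercept_flux``
    is the zero-gradient (ballistic) offset. ``non_fourier`` flags a negative
    slope. ``delta_F`` is filled by barrier analysis where applicable.
    """

    label: str
    gradient_range: tuple[float, float]
    D_eff: float
    kappa_eff: float
    intercept_flux: float
    D_eff_sem: float
    kappa_eff_sem: float
    intercept_sem: float
    n_bins: int
    converged: bool = True
    non_fourier: bool = False
    delta_F: float | None = None
    heat_capacity_per_link: float = DEFAULT_HEAT_CAPACITY
    spacing: float = 0.2


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares for y = a·x + b; returns (params, stderr)."""
    design = np.column_stack([x, np.ones_like(x)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coef
    dof = max(x.size - 2, 1)
    xtwx_inv = np.linalg.inv(design.T @ (design * w[:, None]))
    # scale the weighted covariance by the reduced chi-square
    chi2 = float(np.sum(w * resid**2)) / dof
    cov = xtwx_inv * chi2
    return coef, np.sqrt(np.diag(cov))


def fit_linear_regime(
    stats: GradientBinnedStats,
    gradient_range: tuple[float, float],
    spacing: float = 0.2,
    heat_capacity_per_link: float = DEFAULT_HEAT_CAPACITY,
    *,
    exclude_below: float = 4.0,
    min_bins: int = 3,
    label: str = "",
    abscissa: Literal["mean", "center"] = "mean",
) -> RegimeFit:
    """Weighted linear fit of mean flux versus gradient over one regime.

    Only reliable bins inside ``gradient_range`` (half-open) enter; bins with
    |center| < ``exclude_below`` (K) are excluded to ignore the residual
    ballistic signature around zero gradient. Weights are 1/sem² where sems
    are available, otherwise the fit is unweighted. The slope is reported as
    κ_eff and converted to D_eff via ``spacing`` and the per-link heat
    capacity; the intercept is the ballistic zero-gradient offset.

    By default the abscissa is each bin's within-bin mean gradient, which
    removes the half-bin-width discretization bias of regressing against bin
    centers; ``abscissa="center"`` restores the plain binned-center fit.
    """
    lo, hi = gradient_range
    centers = stats.centers
    sel = (
        stats.reliable
        & (centers >= lo)
        & (centers < hi)
        & (np.abs(centers) >= exclude_below)
        & np.isfinite(stats.mean_flux)
    )
    if int(sel.sum()) < min_bins:
        raise ValueError(
            f"regime {label or gradient_range}: only {int(sel.sum())} reliable bins, "
            f"need {min_bins}"
        )
    x = stats.mean_gradient[sel] if abscissa == "mean" else centers[sel]
    y = stats.mean_flux[sel]
    s = stats.sem_flux[sel]
    if np.all(np.isfinite(s)) and np.all(s > 0):
        w = 1.0 / s**2
    else:
        w = np.ones_like(x)
    (slope, intercept), (slope_se, intercept_se) = _wls_line(x, y, w)
    conv = spacing**2 / heat_capacity_per_link
    return RegimeFit(
        label=label,
        gradient_range=(float(lo), float(hi)),
        D_eff=float(slope * conv),
        kappa_eff=float(slope),
        intercept_flux=float(intercept),
        D_eff_sem=float(slope_se * conv),
        kappa_eff_sem=float(slope_se),
        intercept_sem=float(intercept_se),
        n_bins=int(sel.sum()),
        converged=True,
        non_fourier=bool(slope < 0),
        heat_capacity_per_link=heat_capacity_per_link,
        spacing=spacing,
    )


def segment_regimes(
    stats: GradientBinnedStats,
    boundaries: Sequence[float] = (15.0, 30.0, 50.0, 77.0),
    *,
    exclude_below: float = 4.0,
    include_tail: bool = False,
    **fit_kwargs,
) -> list[RegimeFit]:
    """Fit each gradient regime between successive boundaries independently.

    With the default boundaries the regions are A: [cutoff, 15), B: [15, 30),
    C: [30, 50), D: [50, 77) K; data beyond the last boundary (the
    strong-localization early-time regime) is excluded unless
    ``include_tail`` is set. Regions without enough reliable bins are
    returned unconverged (NaN parameters) rather than dropped.
    """
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    edges = [exclude_below] + bounds
    if include_tail:
        edges.append(float(stats.bin_edges[-1]))
    fits = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        label = chr(ord("A") + i)
        try:
            fits.append(
                fit_linear_regime(
                    stats, (lo, hi), exclude_below=exclude_below, label=label, **fit_kwargs
                )
            )
        except ValueError:
            fits.append(
                RegimeFit(
                    label=label,
                    gradient_range=(float(lo), float(hi)),
                    D_eff=np.nan,
                    kappa_eff=np.nan,
                    intercept_flux=np.nan,
                    D_eff_sem=np.nan,
                    kappa_eff_sem=np.nan,
                    intercept_sem=np.nan,
                    n_bins=0,
                    converged=False,
                )
            )
    return fits


def barrier_from_ratio(
    j_high: float, j_low: float, t_low: float, t_high: float
) -> float:
    """Effective free-energy barrier ΔF (eV) from a high/low flux ratio.

    Inverts the Arrhenius relation
    ``J_H/J_L = exp(−ΔF/k_B T_H + ΔF/k_B T_L)``:

        ΔF = ln(J_H/J_L) / [1/(k_B T_L) − 1/(k_B T_H)].

    A negative result (ratio < 1) is reported as-is and signals inverted
    temperature ordering of the fluxes.
    """
    if j_high <= 0 or j_low <= 0:
        raise ValueError("fluxes must be positive")
    if not 0 < t_low < t_high:
        raise ValueError("need 0 < t_low < t_high")
    denom = 1.0 / (K_B * t_low) - 1.0 / (K_B * t_high)
    return math.log(j_high / j_low) / denom


@dataclass
class BarrierProfile:
    """Per-gradient-bin effective barrier ΔF with propagated uncertainty."""

    centers: np.ndarray
    delta_f: np.ndarray
    sem: np.ndarray
    t_low: np.ndarray
    t_high: np.ndarray


def barrier_profile(
    stats_low: GradientBinnedStats,
    stats_high: GradientBinnedStats,
    *,
    temperatures: Literal["nominal", "empirical"] = "nominal",
    nominal: tuple[float, float] = (250.0, 310.0),
) -> BarrierProfile:
    """Per-bin ΔF from the ratio of high- to low-temperature mean fluxes.

    Bins where either class is unreliable, empty, or non-positive are
    omitted. ``temperatures="nominal"`` (default) uses the fixed class mean
    temperatures (250/310 K), appropriate when activation is governed by the
    bath; ``"empirical"`` uses each bin's mean local temperature
    (bath + mean pair elevation), appropriate when activation follows the
    instantaneous local temperature. Uncertainty is first-order-propagated
    from the flux sems.
    """
    if stats_low.bin_edges.size != stats_high.bin_edges.size or not np.allclose(
        stats_low.bin_edges, stats_high.bin_edges
    ):
        raise ValueError("barrier_profile requires matching bin grids")
    centers, dfs, sems, tls, ths = [], [], [], [], []
    for b in range(stats_low.centers.size):
        if not (stats_low.reliable[b] and stats_high.reliable[b]):
            continue
        jl, jh = stats_low.mean_flux[b], stats_high.mean_flux[b]
        if not (np.isfinite(jl) and np.isfinite(jh)) or jl <= 0 or jh <= 0:
            continue
        if temperatures == "empirical":
            tl = float(stats_low.mean_temperature[b])
            th = float(stats_high.mean_temperature[b])
        else:
            tl, th = nominal
        if not 0 < tl < th:
            continue
        denom = 1.0 / (K_B * tl) - 1.0 / (K_B * th)
        df = math.log(jh / jl) / denom
        sl, sh = stats_low.sem_flux[b], stats_high.sem_flux[b]
        sem = (
            math.sqrt((sh / jh) ** 2 + (sl / jl) ** 2) / denom
            if np.isfinite(sl) and np.isfinite(sh)
            else np.nan
        )
        centers.append(stats_low.centers[b])
        dfs.append(df)
        sems.append(sem)
        tls.append(tl)
        ths.append(th)
    return BarrierProfile(
        centers=np.array(centers),
        delta_f=np.array(dfs),
        sem=np.array(sems),
        t_low=np.array(tls),
        t_high=np.array(ths),
    )


def ensemble_barrier_analysis(
    ensembles_by_bath: Mapping[float, Sequence],
    topology,
    *,
    fit_window: int = 25,
    release_time: float = 1.0,
    transport_phase_end: float = 10.0,
    smooth_window: int = 9,
    bin_width: float = 1.0,
    classes: Mapping[str, tuple[float, float]] | None = None,
    min_count: int = 10,
    temperatures: Literal["nominal", "empirical"] = "nominal",
    nominal: tuple[float, float] = (250.0, 310.0),
) -> tuple[dict[str, GradientBinnedStats], BarrierProfile]:
    """Ensemble-level barrier extraction across bath-temperature classes.

    For each bath temperature the member trajectories are averaged
    (suppressing observation noise by √n), lightly denoised with a
    Savitzky-Golay filter (``smooth_window`` bins, quadratic; 0 disables it)
    — the standard pre-filter when estimating derivatives from noisy series,
    since the rate inversion differentiates the energies — and rates are
    fitted on the free-relaxation segment (t ≥ ``release_time``) with a
    ``fit_window`` of consecutive bins (default 25 bins = 2.5 ps at the
    standard 0.1 ps analysis spacing — wide enough to beat the 1/Δt noise
    amplification of the finite differences, still local relative to the
    relaxation time). Fluxes are collected over the transient transport
    phase (t ≤ ``transport_phase_end``; later bins are equilibrium
    fluctuations that carry no transport signal), pooled, gradient-binned
    per class, and reduced to the per-bin barrier profile.
    """
    from scipy.signal import savgol_filter

    from .coarse_grain import ensemble_mean
    from .master_equation import compute_fluxes, fit_rates
    from .trajectory_io import EnergyTrajectory

    records: list[FluxGradientRecord] = []
    for t_b in sorted(ensembles_by_bath):
        mean = ensemble_mean(ensembles_by_bath[t_b]).window(release_time)
        if smooth_window and mean.n_frames > smooth_window:
            smoothed = np.maximum(
                savgol_filter(mean.energies, smooth_window, 2, axis=1), 0.0
            )
            mean = EnergyTrajectory(
                times=mean.times, energies=smoothed, dof=mean.dof,
                bath_temperature=mean.bath_temperature,
                heater_index=mean.heater_index, ensemble_id=mean.ensemble_id,
            )
        rates = fit_rates(mean, topology, window=fit_window)
        records.extend(
            r
            for r in compute_fluxes(mean, topology, rates)
            if r.bin_time <= transport_phase_end
        )
    stats = bin_by_gradient(records, bin_width, classes, min_count=min_count)
    if not {"low", "high"} <= set(stats):
        raise ValueError("classes must include 'low' and 'high' for barrier analysis")
    bp = barrier_profile(
        stats["low"], stats["high"], temperatures=temperatures, nominal=nominal
    )
    return stats, bp


def tmax_diffusivity(
    profile: TransportProfile,
    spacing: float = 0.2,
    *,
    heater_index: int | None = None,
    refine: bool = True,
    min_residues: int = 3,
):
    """Diffusivity from per-residue peak-arrival times, ``t_max = d²/D``.

    For each non-heater residue the time of maximal elevation is located
    (with parabolic sub-bin refinement over the three neighbouring bins by
    default); D is the origin-constrained least-squares slope of d² versus
    t_max. Residues whose elevation is monotone over the window (peak on a
    boundary bin) are excluded; fewer than ``min_residues`` usable residues
    is an error. Returns ``(D, table)`` where the table lists
    (residue, distance, t_max) rows.

    Note the model follows the stated ``t_max = d²/D`` form with no factor
    of 2, so this estimate absorbs residual ballistic contributions and
    generally exceeds the rate-based ``k·Δx²`` diffusivity.
    """
    h = heater_index or profile.heater_index
    if h is None:
        raise ValueError("heater index unknown; pass heater_index=")
    rows = []
    for j in range(profile.elevation.shape[0]):
        if j + 1 == h:
            continue  # d = 0 carries no information about D
        y = profile.elevation[j]
        i = int(np.argmax(y))
        if i == 0 or i == y.size - 1:
            continue  # monotone/non-peaked within the window
        t = profile.times[i]
        if refine:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                dt_bin = profile.times[i + 1] - profile.times[i]
                t = t + 0.5 * dt_bin * (y0 - y2) / denom
        rows.append((j + 1, abs(j + 1 - h) * spacing, float(t)))
    if len(rows) < min_residues:
        raise ValueError(f"only {len(rows)} peaked residues; need {min_residues}")
    d2 = np.array([r[1] ** 2 for r in rows])
    tm = np.array([r[2] for r in rows])
    if np.sum(tm**2) <= 0:
        raise ValueError("degenerate arrival times")
    diffusivity = float(np.sum(tm * d2) / np.sum(tm**2))
    return diffusivity, rows
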