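# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `heatflow`. Units throughout: energies in eV, temperatures in
K, times in ps, lengths in nm, masses in u; `k_B = 8.617333262e-5 eV/K`.

## The exchange model and its conventions

Residue kinetic energies evolve as

    dE_j/dt = Σ_i k_pair(i,j) [E_i − (f_i/f_j) E_j] − R_j k_s (E_j − E_s,j)

over a contact topology of backbone neighbours `(j, j+1)` and hydrogen-bond
pairs (`(j, j+3)` for a 3₁₀ helix, `(j, j+4)` for an α helix, or an explicit
custom list). Conventions the package commits to:

* **Exchange term.** The pair flux is `k·[E_i − (f_i/f_j) E_j]`. This form
  vanishes exactly at equipartition (`E_j ∝ f_j`), which simultaneously
  fixes the detailed-balance relation `k_ji = (f_i/f_j) k_ij` and guarantees
  that the bath equilibrium is a stationary point of the dynamics. An
  unscaled variant `[E_i − E_j]` (identical whenever the paired residues
  have equal degrees of freedom, as for a homopolymer interior) is available
  via `strict_paper_g=True`.
* **Solvent term.** Written as relaxation toward the bath,
  `−R_j k_s (E_j − E_s,j)` with `E_s,j = (f_j/2) k_B T_B`; `R_j ≥ 1` is a
  geometric surface factor (default 1.5 at the termini, 1 elsewhere)
  expressing the larger solvent-exposed area of terminal residues.
* **Degrees of freedom.** `f_j = 3 N_j` with no constraint correction;
  callers with constrained force fields can override per residue.
* **Indices.** Residues are 1-based in every file and interface.

## Rate inversion

Per analysis bin `n` (default width 0.1 ps) the unknown rates
`k = (k_{1,2}, …, k_{N−1,N}, k_HB)` solve

    min_{k ≥ 0} ½ ‖G k − d‖²,
    d_j = [E_j(t_n) − E_j(t_{n−1})]/Δt + R_j k_s (Ē_j − E_s,j),

with rows indexed by residues, backbone column m carrying `∓[Ē_i − (f_i/f_j)Ē_j]`
in rows i = m, j = m+1, and one shared hydrogen-bond column summing the
analogous terms. The solver is deterministic active-set NNLS.

Numerical choices:

* **Midpoint evaluation.** `Ē = (E(t_{n−1}) + E(t_n))/2`. The
  finite-difference left side is centered, so midpoint energies make the
  discretization second order; right-endpoint evaluation (`energy_eval="right"`)
  incurs a first-order bias of roughly `k·Δt/2` (≈ 7% at `k = 1.5 ps⁻¹`,
  `Δt = 0.1 ps`) and is provided only for comparison.
* **Windowed identifiability.** Exchange conserves energy, so every column
  of a single bin's `G` sums to zero: with the shared `k_HB` there are N
  unknowns but at most rank N−1, and the per-bin minimizer is a segment, not
  a point — an exact-data fit can return an arbitrary vertex of that
  segment. `fit_rates` therefore stacks a centered sliding window of
  `window` consecutive bins (default 3) into one solve, treating the rates
  as constant across the window — the same locality assumption that
  justifies the coarse-graining scale itself. Two distinct energy
  configurations restore full rank; `window=1` reproduces the strict
  single-bin formulation. On noiseless constant-rate data the windowed fit
  recovers all rates to ≤ 4.3% per bin (≤ 0.8% beyond the first few bins
  after heater release).
* **Solvent rate.** `k_s(t_n)` is estimated per bin *before* the NNLS from
  the total energy budget: exchange is conservative, so the drift of
  `Σ_j E_j` is attributable to the solvent alone,
  `k_s = −[Σ_j ΔE_j/Δt] / [Σ_j R_j (Ē_j − E_s,j)]`. This closure is exact on
  noiseless model data. A per-residue ratio-sum estimator
  (`method="printed"`, `−(1/Δt) Σ_j ΔE_j/(E_j − E_s,j)` with a guard
  `ε = 1e-6 eV` on small denominators) is retained for comparison; note that
  for M residues relaxing uniformly it returns ≈ M·k_s, and under active
  exchange it is dominated by small-denominator terms, so it is not the
  default. Negative estimates are clamped to zero and flagged.
* **Degeneracy.** Bins whose stacked `G` has no entries above `1e-11` of the
  trajectory's energy scale (e.g. at equilibrium) are flagged and return
  zero rates.
* **Driven bins.** During the heater window the heated residue is externally
  driven and the free master equation does not govern its row; analyses
  should fit the free-relaxation segment (`trajectory.window(t_release)`).

## Fluxes, gradients, and landscape statistics

Fluxes are evaluated per coupled pair per bin with the fitted rate and the
same midpoint energies, oriented positive *away from the heater residue*;
pairs straddling a mid-chain heater at equal distance are reported in both
directions. The effective temperature gradient is
`Δ_ij T_eff = 2[E_i − (f_i/f_j)E_j]/(3 N k_B)` with `N` the atom count of the
accepting (downstream) residue.

Records are block-averaged in uniform gradient bins (default 1.0 K,
half-open), per bath-temperature class (defaults: low 230–270 K, high
290–330 K; records between classes are dropped). Bins with fewer than 10
records are flagged unreliable. Regime fits are weighted least squares
(weights `1/sem²`, falling back to unweighted when sems are unavailable) of
mean flux against the *within-bin mean* gradient — regressing on bin centers
instead (`abscissa="center"`) adds a half-bin discretization bias that is
visible in the zero-gradient intercept on clean data. Bins with
`|Δ_ij T_eff| < 4 K` are excluded from the fits: around zero gradient the
flux is dominated by the residual ballistic component rather than Fourier
transport. The fitted slope is reported as the per-link conductivity
`κ_eff` (eV K⁻¹ ps⁻¹) and converted to a diffusivity through
`D_eff = κ_eff · Δx² / C_link`; because the underlying data never fix the
inter-residue spacing or per-link heat capacity, both constants are explicit
parameters (defaults `Δx = 0.2 nm`, `C_link = (3/2)·13·k_B`) and are always
reported with the result.

Regime segmentation fits each gradient interval between the supplied
boundaries (defaults 15/30/50/77 K) independently; data beyond the last
boundary — dominated by the earliest strongly localized dynamics — are
excluded unless `include_tail` is set.

## Barriers

Comparing class flux curves through the Arrhenius form gives

    ΔF = ln(J_H/J_L) / [1/(k_B T_L) − 1/(k_B T_H)]

per gradient bin, with first-order error propagation from the flux sems.
Default class temperatures are the nominal means 250/310 K, appropriate when
activation is governed by the bath; the elevation-corrected empirical per-bin
temperatures (`temperatures="empirical"`) suit models where rates follow the
instantaneous local temperature. Negative barriers (inverted flux ordering)
are reported, not suppressed.

`ensemble_barrier_analysis` packages the recommended ensemble workflow:

1. average the members of each bath's ensemble (observation noise ↓ √n);
2. denoise with a Savitzky–Golay filter (9 bins, quadratic; the inversion
   differentiates the series, amplifying noise by 1/Δt, and NNLS clipping of
   noise-dominated bins otherwise compresses the high/low flux ratio and
   biases barriers low by ~8% under the default study conditions);
3. fit rates with a 25-bin (2.5 ps) window — still local relative to the
   ~20 ps solvent relaxation, wide enough to average the finite-difference
   noise;
4. keep flux records from the transient transport phase (release to 10 ps;
   later bins are equilibrium fluctuations with no transport signal);
5. bin per class and form the barrier profile.

Under the standard recovery conditions (ΔG = 50 meV, Ω = 5 ps⁻¹, six baths
230–330 K, 500 members each, noise scale 0.3) this recovers a flat barrier
level within 10% of truth across seeds.

## Profiles and auxiliary estimators

* `block_average`: left-closed windows anchored at the first frame, output
  at window centers, trailing partial window dropped — deterministic and
  grid-independent.
* `ensemble_profile` / `profile_difference`: per-residue mean kinetic
  temperature elevation `ΔT_B,j(t)` with standard errors (sample sd/√n;
  quadrature propagation for differences). Subensemble membership is an
  input label; no structural clustering is performed.
* `front_velocity`: arrival = first bin with two consecutive elevations
  above threshold (default 5 K; single-bin spikes rejected); velocity from
  the distance-vs-arrival-time slope. A curvature check (linear vs quadratic
  arrival scaling) flags diffusive profiles, whose `t ∝ d²` arrivals would
  otherwise masquerade as a slow front. Because the thermal front of a real
  profile has no sharp edge, this is a best-effort estimator whose value
  depends on the threshold.
* `tmax_diffusivity`: inverts the peak-arrival model `t_max = d²/D` (stated
  without the 1-D point-source factor of 2; the implementation follows that
  form, so its values are systematically larger than `k·Δx²` and absorb any
  ballistic early-arrival component). Peak times use parabolic sub-bin
  refinement; residues whose maximum sits on a window boundary are excluded.
* `net_heat`: cumulative rectangle-rule sum of a pair's flux (trapezoid
  optional).

## Synthetic generators

`simulate_master_equation` integrates the exchange model with classical RK4
(internal step 1e-3 ps, recorded every 0.1 ps by default). The heater
protocol pins the heated residue's energy at `(f/2)k_B(T_B + ΔT)` (defaults
ΔT = 670 K for 1 ps — an energy deposition comparable to an enzymatic
reaction quantum) and then releases the whole chain. Rates are constant, or
Arrhenius `Ω exp(−ΔG/k_B T)` with `T` either the bath temperature (constant
in time, Arrhenius across conditions — the default) or the instantaneous
pair-mean kinetic temperature (`local_temperature=True`). Note the shared
`k_HB` ansatz is misspecified under local-temperature activation at early
times, when hydrogen-bond partners sit at very different temperatures.

Ensemble members share the deterministic solution and differ by independent
Gaussian observation noise per recorded energy, with standard deviation
`noise_scale · √(f_j/2) k_B T_j` — the canonical equipartition fluctuation of
a residue's kinetic energy, attenuated by `noise_scale`. The default 0.3
emulates the variance reduction from averaging kinetic energies over a
100 fs analysis bin, within which velocities decorrelate on the ~10 fs
scale. Noise streams derive from `(master seed, bath temperature, member
index)`, so ensembles are reproducible, order-independent, and uncorrelated
across bath conditions. What this noise model deliberately omits: temporal
correlation of the fluctuations, conformational heterogeneity between
members, anharmonic coupling, and solvent-shell dynamics — so passing
recovery tests demonstrates estimator correctness under the model's own
assumptions, not robustness to everything real simulation data contains.

`simulate_lattice` is a desk-scale stand-in for all-atom NEMD: a 1-D FPU-β
chain (harmonic + quartic nearest-neighbour bonds, free ends) integrated by
velocity Verlet, with a Langevin (BAOAB) heater segment during the heating
window and microcanonical dynamics afterwards. Defaults (64 sites, m = 12 u,
a = 0.15 nm, k = 10 eV/nm², β = 200 eV/nm⁴, 8 sites per pseudo-residue) give
a sound speed `c = a√(k/m) ≈ 1.35 nm/ps`, in the range of backbone
ballistic-front velocities. The timestep must satisfy the stability bound
`dt < 2/ω_max`; the harmonic-limit conservation checks use `dt = 1e-5 ps`,
at which the symplectic energy oscillation stays below 1e-8 relative over
100 ps.

`make_fixture_suite` writes the standard battery (noiseless constant-rate
and noisy Arrhenius ensembles at six baths 230–330 K, plus one lattice run)
with a manifest of every generating parameter; identical seeds give
byte-identical files.

## Problem sizes used in the validation suite

The shipped tests and `scripts/acceptance.py` use 10-residue 3₁₀ chains,
25 ps trajectories at 0.1 ps resolution, ensembles of up to 500 members per
bath (six baths), 100 random solver-oracle systems, and lattice runs of
64–400 sites up to 400 ps. These sizes make every recovery target
statistically decisive while keeping the full suite in the minutes range on
a single CPU.

## Known limitations

* The per-bin inversion assumes rates constant over the stacking window;
  genuinely sub-100-fs rate variation is invisible by construction.
* With observation noise, fitted rates in near-equilibrium bins are
  noise-dominated and non-negativity clipping biases them upward; the
  ensemble workflow (averaging, smoothing, transport-phase selection)
  mitigates but does not eliminate this. Gradient noise also produces
  regression dilution in flux-gradient fits for small ensembles.
* The zero-gradient ballistic intercept is a fit extrapolation; it is
  quantitative only when the linear regime is well populated outside the
  4 K exclusion zone.
* Hydrogen-bond transport is summarized by one shared rate per bin;
  per-pair hydrogen-bond rates are outside the default model.
* All dynamics are classical; no quantum corrections to low-temperature
  rates are attempted.
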