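"""Topology construction, solvent-rate estimation, system assembly, NNLS fit,
fluxes, and effective gradients."""

import numpy as np
import pytest
from scipy.optimize import nnls

import heatflow as hf
from heatflow.constants import K_B
from heatflow.master_equation import SolventRate, assemble_system, solvent_rate

from conftest import make_equilibrium_trajectory


class TestBuildTopology:
    def test_310_pairs(self):
        topo = hf.build_topology(10, "310")
        assert topo.backbone_pairs == [(j, j + 1) for j in range(1, 10)]
        assert topo.hbond_pairs == [(j, j + 3) for j in range(1, 8)]

    def test_alpha_pairs(self):
        topo = hf.build_topology(10, "alpha")
        assert topo.hbond_pairs == [(j, j + 4) for j in range(1, 7)]

    def test_two_residues_backbone_only(self):
        topo = hf.build_topology(2, "310")
        assert topo.backbone_pairs == [(1, 2)]
        assert topo.hbond_pairs == []
        assert topo.n_unknowns == 1

    def test_custom_pair_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            hf.build_topology(10, "custom", [(1, 12)])

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            hf.build_topology(10, "custom", [(1, 5), (1, 5)])

    def test_terminal_surface_factor(self):
        topo = hf.build_topology(5, "310")
        assert topo.surface_factor[0] == topo.surface_factor[-1] == 1.5
        assert np.all(topo.surface_factor[1:-1] == 1.0)


class TestDetailedBalance:
    def test_equal_dof_symmetric(self):
        assert hf.detailed_balance_reverse(2.0, 39, 39) == 2.0

    @pytest.mark.parametrize("k_ij,f_i,f_j", [(2.0, 39, 78), (0.7, 30, 45), (1.0, 3, 99)])
    def test_equipartition_stationary(self, k_ij, f_i, f_j):
        # pair flux k_ij E_i - k_ji E_j vanishes at E propto f
        k_ji = hf.detailed_balance_reverse(k_ij, f_i, f_j)
        c = 0.013  # eV per dof
        assert k_ij * (f_i * c) - k_ji * (f_j * c) == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            hf.detailed_balance_reverse(1.0, 0, 39)


class TestSolventRate:
    def test_unchanged_energies_give_zero(self):
        tr = make_equilibrium_trajectory()
        out = solvent_rate(tr, 1)
        assert out.value == 0.0

    def test_all_at_bath_guarded(self):
        tr = make_equilibrium_trajectory()
        out = solvent_rate(tr, 1, method="printed")
        assert out == SolventRate(0.0, False, tr.n_residues)

    def test_printed_sign_convention(self):
        # residue 1 decays E_s+2d -> E_s+d over one bin; residue 2 pinned at
        # E_s (guarded out): the printed sum gives -1, flipped -> 1/dt.
        t_b, dof = 300.0, np.array([39, 39])
        e_s = 0.5 * dof * K_B * t_b
        d = 0.01
        energies = np.array([[e_s[0] + 2 * d, e_s[0] + d], [e_s[1], e_s[1]]])
        tr = hf.EnergyTrajectory(
            times=[0.0, 0.1], energies=energies, dof=dof, bath_temperature=t_b
        )
        out = solvent_rate(tr, 1, method="printed")
        assert out.value == pytest.approx(1 / 0.1, rel=1e-12)
        assert out.n_omitted == 1

    def test_balance_method_matches_pure_relaxation(self, topo10):
        # oracle: forward-simulate pure solvent relaxation, recover k_s
        model = hf.KineticModel.constant_rates(topo10, 0.0, 0.0, 0.2, 300.0)
        tr = hf.simulate_master_equation(
            model, hf.HeaterProtocol(), 1, 0, total_time=5.0, noise_scale=0.0
        )[0].window(1.0)
        for n in (1, 10, 30):
            out = solvent_rate(tr, n, topology=topo10)
            assert out.value == pytest.approx(0.2, rel=1e-3)

    def test_predecessor_required(self):
        tr = make_equilibrium_trajectory()
        with pytest.raises(IndexError):
            solvent_rate(tr, 0)


class TestAssembleSystem:
    def test_equilibrium_null_case(self, topo10):
        tr = make_equilibrium_trajectory(n_res=10)
        g, d = assemble_system(tr, topo10, 1, k_s=0.0)
        assert np.allclose(g, 0.0, atol=1e-15)
        assert np.allclose(d, 0.0, atol=1e-15)

    def test_two_residue_backbone_column(self):
        tr = hf.EnergyTrajectory(
            times=[0.0, 0.1],
            energies=[[2.0, 2.0], [1.0, 1.0]],
            dof=[39, 39],
            bath_temperature=300.0,
        )
        topo = hf.build_topology(2, "custom", [])
        g, d = assemble_system(tr, topo, 1, k_s=0.0)
        assert g.shape == (2, 1)
        assert np.allclose(g[:, 0], [-1.0, 1.0])

    def test_310_system_shape(self, topo10, free_segment):
        g, d = assemble_system(free_segment, topo10, 1, k_s=0.05)
        assert g.shape == (10, 10)  # 9 backbone columns + shared hbond column
        assert d.shape == (10,)
        # exchange conserves energy: every column sums to zero
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-14)

    def test_strict_paper_mode_equals_scaled_for_equal_dof(self, topo10, free_segment):
        g1, _ = assemble_system(free_segment, topo10, 5, k_s=0.0)
        g2, _ = assemble_system(free_segment, topo10, 5, k_s=0.0, strict_paper_g=True)
        assert np.allclose(g1, g2)


class TestFitRates:
    def test_equilibrium_flagged_degenerate(self, topo10):
        tr = make_equilibrium_trajectory(n_res=10, n_frames=8)
        rates = hf.fit_rates(tr, topo10)
        assert np.all(rates.degenerate)
        assert np.all(rates.k_backbone == 0.0)

    def test_three_residue_single_bin_matches_grid_oracle(self):
        # 2 unknowns, window=1: brute-force dense-grid minimizer
        topo = hf.build_topology(3, "custom", [])
        model = hf.KineticModel.constant_rates(topo, 1.2, 0.0, 0.0, 300.0)
        tr = hf.simulate_master_equation(
            model, hf.HeaterProtocol(duration=0.5), 1, 0, total_time=1.0, noise_scale=0.0
        )[0].window(0.5)
        rates = hf.fit_rates(tr, topo, window=1)
        n = 2
        g, d = assemble_system(tr, topo, n, rates.k_solvent[n - 1])
        grid = np.linspace(0, 3, 601)
        kk1, kk2 = np.meshgrid(grid, grid, indexing="ij")
        obj = np.zeros_like(kk1)
        for row in range(g.shape[0]):
            obj += (g[row, 0] * kk1 + g[row, 1] * kk2 - d[row]) ** 2
        best = np.unravel_index(np.argmin(obj), obj.shape)
        oracle = np.array([grid[best[0]], grid[best[1]]])
        assert np.all(np.abs(rates.k_backbone[:, n - 1] - oracle) <= grid[1] - grid[0])

    def test_scale_covariance(self, free_segment, topo10, fitted_rates):
        c = 7.3
        scaled = hf.EnergyTrajectory(
            times=free_segment.times,
            energies=c * free_segment.energies,
            dof=free_segment.dof,
            bath_temperature=c * free_segment.bath_temperature,
            heater_index=free_segment.heater_index,
        )
        rates_c = hf.fit_rates(scaled, topo10)
        # identical up to active-set roundoff in the constrained solver
        assert np.allclose(rates_c.k_backbone, fitted_rates.k_backbone, rtol=1e-6, atol=1e-9)
        assert np.allclose(rates_c.k_hbond, fitted_rates.k_hbond, rtol=1e-6, atol=1e-9)

    def test_kkt_conditions(self, free_segment, topo10):
        # active components: gradient >= 0; free components: gradient ~ 0
        rates = hf.fit_rates(free_segment, topo10, window=1)
        for b in (5, 50, 150):
            n = b + 1
            g, d = assemble_system(free_segment, topo10, n, rates.k_solvent[b])
            k = np.concatenate([rates.k_backbone[:, b], [rates.k_hbond[b]]])
            grad = g.T @ (g @ k - d)
            scale = max(np.abs(grad).max(), 1.0)
            free = k > 1e-12
            assert np.all(grad[free] / scale >= -1e-10)
            assert np.all(np.abs(grad[free]) / scale <= 1e-8)
            assert np.all(grad[~free] / scale >= -1e-10)

    def test_nonnegativity_always(self, fitted_rates):
        assert np.all(fitted_rates.k_backbone >= 0)
        assert np.all(fitted_rates.k_hbond >= 0)
        assert np.all(fitted_rates.k_solvent >= 0)

    def test_conservation_closure(self, free_segment, topo10, fitted_rates):
        # fitted model reproduces each residue's energy budget within the
        # stored residual on noiseless data
        for b in (3, 40, 120):
            n = b + 1
            g, d = assemble_system(free_segment, topo10, n, fitted_rates.k_solvent[b])
            k = np.concatenate(
                [fitted_rates.k_backbone[:, b], [fitted_rates.k_hbond[b]]]
            )
            # windowed estimate may differ slightly from the single-bin
            # minimizer; allow discretization-level slack
            assert np.linalg.norm(g @ k - d) <= max(
                5 * fitted_rates.residual_norm[b], 1e-3 * np.linalg.norm(d) + 1e-12
            )


class TestComputeFluxes:
    def test_zero_rate_zero_flux(self, free_segment, topo10):
        rates = hf.fit_rates(free_segment, topo10)
        zero = hf.RateFitSeries(
            bin_times=rates.bin_times,
            k_backbone=np.zeros_like(rates.k_backbone),
            k_hbond=np.zeros_like(rates.k_hbond),
            k_solvent=rates.k_solvent,
            residual_norm=rates.residual_norm,
            feasible=rates.feasible,
            degenerate=rates.degenerate,
        )
        records = hf.compute_fluxes(free_segment, topo10, zero)
        assert all(r.flux == 0.0 for r in records)

    def test_equipartition_pair_zero_flux(self, topo10):
        tr = make_equilibrium_trajectory(n_res=10, n_frames=8)
        rates = hf.fit_rates(tr, topo10)
        records = hf.compute_fluxes(tr, topo10, rates)
        assert all(abs(r.flux) < 1e-15 for r in records)
        assert all(abs(r.gradient) < 1e-12 for r in records)

    def test_sign_convention_away_from_heater(self):
        # heater at residue 1; E_1 - E_2 = 0.1 eV, k = 1/ps -> J = +0.1 eV/ps
        topo = hf.build_topology(2, "custom", [])
        tr = hf.EnergyTrajectory(
            times=[0.0, 0.1],
            energies=[[0.6, 0.6], [0.5, 0.5]],
            dof=[39, 39],
            bath_temperature=300.0,
            heater_index=1,
        )
        rates = hf.RateFitSeries(
            bin_times=[0.05], k_backbone=[[1.0]], k_hbond=[0.0], k_solvent=[0.0],
            residual_norm=[0.0], feasible=[True], degenerate=[False],
        )
        (rec,) = hf.compute_fluxes(tr, topo, rates)
        assert rec.pair == (1, 2)
        assert rec.flux == pytest.approx(0.1, rel=1e-12)

    def test_equidistant_pair_reported_both_ways(self):
        # hydrogen-bond pair (1,5) straddles a mid-chain heater at residue 3
        topo = hf.build_topology(5, "custom", [(1, 5)])
        tr = make_equilibrium_trajectory(n_res=5, n_frames=2)
        tr.heater_index = 3
        rates = hf.RateFitSeries(
            bin_times=[0.05], k_backbone=np.ones((4, 1)), k_hbond=[1.0],
            k_solvent=[0.0], residual_norm=[0.0], feasible=[True], degenerate=[False],
        )
        records = hf.compute_fluxes(tr, topo, rates)
        pairs = {r.pair for r in records if r.channel == "hbond"}
        assert pairs == {(1, 5), (5, 1)}


class TestEffectiveGradient:
    def test_zero_at_equipartition(self):
        e_j = 0.5
        assert hf.effective_gradient((39 / 78) * e_j, e_j, 39, 78, 13) == 0.0

    def test_equal_dof_inversion(self):
        delta = 1.5 * 13 * K_B * 10.0  # (3/2) N k_B * 10 K
        assert hf.effective_gradient(0.5 + delta, 0.5, 39, 39, 13) == pytest.approx(
            10.0, rel=1e-12
        )

    def test_arithmetic_oracle(self):
        # 2*0.01 / (3*13*k_B) = 5.951 K
        val = hf.effective_gradient(0.51, 0.50, 39, 39, 13)
        assert val == pytest.approx(2 * 0.01 / (3 * 13 * K_B), rel=1e-12)
        assert val == pytest.approx(5.951, rel=1e-3)

    def test_invalid_atom_count(self):
        with pytest.raises(ValueError):
            hf.effective_gradient(1.0, 1.0, 39, 39, 0)
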