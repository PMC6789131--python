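"""Gradient binning, regime fits, barrier extraction, peak-arrival diffusivity."""

import math

import numpy as np
import pytest

import heatflow as hf
from heatflow.constants import K_B
from heatflow.coarse_grain import TransportProfile
from heatflow.landscape_analysis import DEFAULT_HEAT_CAPACITY
from heatflow.master_equation import FluxGradientRecord


def _rec(grad, flux, t_b=250.0, elev=0.0, rate=1.0, t=0.5):
    return FluxGradientRecord(
        bin_time=t, pair=(1, 2), flux=flux, gradient=grad, mean_elevation=elev,
        bath_temperature=t_b, channel="backbone", rate=rate,
    )


class TestBinByGradient:
    def test_single_record_half_open_bin(self):
        stats = hf.bin_by_gradient([_rec(7.3, 1.0)], 1.0, {"low": (230, 270)}, min_count=1)
        st = stats["low"]
        occupied = np.nonzero(st.counts)[0]
        assert occupied.size == 1
        b = occupied[0]
        assert st.bin_edges[b] == pytest.approx(7.0)
        assert st.bin_edges[b + 1] == pytest.approx(8.0)

    def test_mean_and_sem(self):
        stats = hf.bin_by_gradient(
            [_rec(5.2, 1.0), _rec(5.7, 3.0)], 1.0, {"low": (230, 270)}, min_count=1
        )
        st = stats["low"]
        b = np.nonzero(st.counts)[0][0]
        assert st.mean_flux[b] == pytest.approx(2.0)
        assert st.sem_flux[b] == pytest.approx(1.0)

    def test_partition_gap_excludes_280K(self):
        stats = hf.bin_by_gradient([_rec(5.0, 1.0, t_b=280.0)], 1.0)
        assert stats["low"].counts.sum() == 0
        assert stats["high"].counts.sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        recs = [
            _rec(g, f, t_b=tb)
            for g, f, tb in zip(
                rng.uniform(-3, 40, 500),
                rng.normal(size=500),
                rng.choice([230.0, 250.0, 310.0, 330.0], 500),
            )
        ]
        stats = hf.bin_by_gradient(recs, 1.0)
        n_low = sum(1 for r in recs if 230 <= r.bath_temperature <= 270)
        n_high = sum(1 for r in recs if 290 <= r.bath_temperature <= 330)
        assert stats["low"].counts.sum() == n_low
        assert stats["high"].counts.sum() == n_high

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError):
            hf.bin_by_gradient([], 1.0)


def _line_records(a, b, rng, n=600, gmax=30.0, sigma=0.0):
    out = []
    for _ in range(n):
        g = rng.uniform(0.5, gmax)
        j = a * g + b + (sigma and rng.normal(0, sigma))
        out.append(_rec(g, j))
    return out


class TestFitLinearRegime:
    def test_exact_line_recovered(self):
        rng = np.random.default_rng(2)
        a, b = 3.2e-4, 5.0e-3
        stats = hf.bin_by_gradient(
            _line_records(a, b, rng), 1.0, {"low": (230, 270)}, min_count=1
        )
        fit = hf.fit_linear_regime(stats["low"], (4.0, 30.0))
        assert fit.kappa_eff == pytest.approx(a, rel=1e-10)
        assert fit.intercept_flux == pytest.approx(b, rel=1e-10)

    def test_diffusivity_conversion(self):
        rng = np.random.default_rng(2)
        a = 3.9e-3
        stats = hf.bin_by_gradient(
            _line_records(a, 0.0, rng), 1.0, {"low": (230, 270)}, min_count=1
        )
        fit = hf.fit_linear_regime(stats["low"], (4.0, 30.0), spacing=0.2)
        assert fit.D_eff == pytest.approx(a * 0.2**2 / DEFAULT_HEAT_CAPACITY, rel=1e-9)

    def test_offset_recovered_with_noise(self):
        rng = np.random.default_rng(8)
        j0 = 2.0e-2
        recs = _line_records(3e-4, j0, rng, n=4000, sigma=2e-3)
        stats = hf.bin_by_gradient(recs, 1.0, {"low": (230, 270)}, min_count=10)
        fit = hf.fit_linear_regime(stats["low"], (4.0, 30.0))
        assert abs(fit.intercept_flux - j0) <= 2 * fit.intercept_sem

    def test_insufficient_bins_rejected(self):
        stats = hf.bin_by_gradient([_rec(5.0, 1.0)], 1.0, {"low": (230, 270)}, min_count=1)
        with pytest.raises(ValueError, match="reliable bins"):
            hf.fit_linear_regime(stats["low"], (4.0, 30.0))

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        recs = _line_records(3e-4, 1e-3, rng, n=800, sigma=1e-3)
        s1 = hf.bin_by_gradient(recs, 1.0, {"low": (230, 270)})
        s2 = hf.bin_by_gradient(recs[::-1], 1.0, {"low": (230, 270)})
        f1 = hf.fit_linear_regime(s1["low"], (4.0, 30.0))
        f2 = hf.fit_linear_regime(s2["low"], (4.0, 30.0))
        assert f1.kappa_eff == pytest.approx(f2.kappa_eff, rel=1e-12)
        assert f1.intercept_flux == pytest.approx(f2.intercept_flux, rel=1e-12)


class TestSegmentRegimes:
    def _stats(self):
        rng = np.random.default_rng(4)
        recs = _line_records(3e-4, 0.0, rng, n=8000, gmax=90.0, sigma=1e-3)
        return hf.bin_by_gradient(recs, 1.0, {"low": (230, 270)})["low"]

    def test_default_boundaries_give_four_regions(self):
        fits = hf.segment_regimes(self._stats())
        assert [f.label for f in fits] == ["A", "B", "C", "D"]
        assert fits[0].gradient_range == (4.0, 15.0)
        assert fits[1].gradient_range == (15.0, 30.0)
        assert fits[2].gradient_range == (30.0, 50.0)
        assert fits[3].gradient_range == (50.0, 77.0)

    def test_tail_region_optional(self):
        fits = hf.segment_regimes(self._stats(), boundaries=[10.0], include_tail=True)
        assert len(fits) == 2
        fits = hf.segment_regimes(self._stats(), boundaries=[10.0])
        assert len(fits) == 1

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError):
            hf.segment_regimes(self._stats(), boundaries=[30.0, 15.0])

    def test_empty_region_unconverged(self):
        fits = hf.segment_regimes(self._stats(), boundaries=[15.0, 30.0, 200.0, 300.0])
        assert not fits[2].converged or fits[2].n_bins == 0 or not fits[3].converged


class TestBarrierFromRatio:
    def test_equal_fluxes_zero_barrier(self):
        assert hf.barrier_from_ratio(1.0, 1.0, 250.0, 310.0) == 0.0

    def test_printed_ratio_oracle(self):
        # ln(1.2) / (1/(k_B 250) - 1/(k_B 310)) ~ 2.03e-2 eV
        df = hf.barrier_from_ratio(1.2, 1.0, 250.0, 310.0)
        denom = 1 / (K_B * 250) - 1 / (K_B * 310)
        assert df == pytest.approx(math.log(1.2) / denom, rel=1e-12)
        assert df == pytest.approx(2.03e-2, rel=1e-2)

    @pytest.mark.parametrize("dg", [0.005, 0.05, 0.3])
    def test_arrhenius_inverse_identity(self, dg):
        t_l, t_h = 250.0, 310.0
        ratio = math.exp(-dg / (K_B * t_h) + dg / (K_B * t_l))
        assert hf.barrier_from_ratio(ratio, 1.0, t_l, t_h) == pytest.approx(dg, rel=1e-10)

    def test_inverted_ordering_negative(self):
        assert hf.barrier_from_ratio(0.8, 1.0, 250.0, 310.0) < 0

    def test_zero_flux_rejected(self):
        with pytest.raises(ValueError):
            hf.barrier_from_ratio(0.0, 1.0, 250.0, 310.0)


class TestBarrierProfile:
    def _stats_pair(self, dg=0.0, n=400):
        rng = np.random.default_rng(6)
        k_l = math.exp(-dg / (K_B * 250.0))
        k_h = math.exp(-dg / (K_B * 310.0))
        grads = rng.uniform(0.5, 20, n)  # shared so the per-bin ratio is exact
        low = [_rec(g, k_l * 1e-3 * g, t_b=250.0) for g in grads]
        high = [_rec(g, k_h * 1e-3 * g, t_b=310.0) for g in grads]
        stats = hf.bin_by_gradient(low + high, 1.0)
        return stats["low"], stats["high"]

    def test_identical_curves_zero_barrier(self):
        lo, hi = self._stats_pair(dg=0.0)
        bp = hf.barrier_profile(lo, hi)
        assert np.allclose(bp.delta_f, 0.0, atol=1e-9)

    def test_known_barrier_flat_profile(self):
        lo, hi = self._stats_pair(dg=0.05)
        bp = hf.barrier_profile(lo, hi, temperatures="nominal")
        assert bp.centers.size >= 10
        assert np.allclose(bp.delta_f, 0.05, rtol=1e-6)

    def test_unreliable_bins_omitted(self):
        lo, hi = self._stats_pair(dg=0.0, n=30)  # sparse -> some bins below min_count
        bp = hf.barrier_profile(lo, hi)
        assert bp.centers.size < lo.centers.size

    def test_mismatched_grids_rejected(self):
        lo, _ = self._stats_pair()
        _, hi = self._stats_pair(n=100)
        if lo.bin_edges.size != hi.bin_edges.size:
            with pytest.raises(ValueError):
                hf.barrier_profile(lo, hi)


class TestTmaxDiffusivity:
    def _peaked_profile(self, d_true=0.02, n_res=8, spacing=0.2, heater=1):
        times = 0.05 + 0.1 * np.arange(400)
        elev = np.zeros((n_res, times.size))
        for j in range(n_res):
            d = abs(j + 1 - heater) * spacing
            if d == 0:
                elev[j] = np.exp(-times)  # heater: monotone decay
            else:
                t_peak = d**2 / d_true
                elev[j] = np.exp(-0.5 * ((times - t_peak) / 0.8) ** 2)
        return TransportProfile(
            times=times, elevation=elev, sem=np.zeros_like(elev),
            n_members=1, heater_index=heater,
        )

    def test_exact_model_inversion(self):
        prof = self._peaked_profile(d_true=0.02)
        d, rows = hf.tmax_diffusivity(prof, spacing=0.2)
        assert d == pytest.approx(0.02, rel=1e-3)

    def test_heater_excluded(self):
        prof = self._peaked_profile()
        _, rows = hf.tmax_diffusivity(prof, spacing=0.2)
        assert all(r[0] != 1 for r in rows)

    def test_monotone_residues_excluded_and_min_count(self):
        times = 0.05 + 0.1 * np.arange(50)
        elev = np.tile(times, (4, 1))  # all monotone
        prof = TransportProfile(
            times=times, elevation=elev, sem=np.zeros_like(elev),
            n_members=1, heater_index=1,
        )
        with pytest.raises(ValueError):
            hf.tmax_diffusivity(prof, spacing=0.2)

    def test_tmax_exceeds_rate_based_with_ballistic_term(self, topo10):
        # pure diffusion: t_max-based D comparable to k (dx)^2; adding a
        # ballistic (early arrival) component raises the t_max estimate
        model = hf.KineticModel.constant_rates(topo10, 1.5, 0.0, 0.05, 300.0)
        trajs = hf.simulate_master_equation(
            model, hf.HeaterProtocol(), 1, 0, total_time=25.0, noise_scale=0.0
        )
        prof = hf.ensemble_profile(trajs)
        d_diff, _ = hf.tmax_diffusivity(prof, spacing=0.2)
        # shift peaks earlier to mimic a ballistic front contribution
        shifted = TransportProfile(
            times=prof.times,
            elevation=np.roll(prof.elevation, -8, axis=1),
            sem=prof.sem, n_members=1, heater_index=prof.heater_index,
        )
        d_ball, _ = hf.tmax_diffusivity(shifted, spacing=0.2)
        assert d_ball > d_diff
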