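"""Siegert relation, decay-spectrum inversion and peak extraction."""

import numpy as np
import pytest
from scipy.optimize import nnls

from scpsizer import (
    CorrelationFunction,
    DlsAcquisitionSpec,
    DlsModel,
    PopulationMode,
    SizeDistribution,
    diffusion_coefficient_sphere,
    estimate_beta,
    g1_from_g2,
    invert_decay_spectrum,
    peaks_from_distribution,
    rh_from_gamma,
    scattering_vector,
    simulate_dls_g2,
)
from scpsizer.dls import default_gamma_grid


LAGS = np.logspace(-6, 0, 120)


class TestScatteringVector:
    def test_worked_value(self, water):
        assert scattering_vector(water, 660e-9, 90.0) == pytest.approx(1.791e7, rel=1e-3)

    def test_backscatter_limit(self, water):
        full = 4 * np.pi * water.refractive_index / 660e-9
        assert scattering_vector(water, 660e-9, 179.99) == pytest.approx(full, rel=1e-6)

    def test_halving_wavelength_doubles_q(self, water):
        assert scattering_vector(water, 330e-9) == pytest.approx(
            2 * scattering_vector(water, 660e-9), rel=1e-12
        )

    @pytest.mark.parametrize("angle", [0.0, 180.0, -10.0])
    def test_out_of_range_angle_rejected(self, angle, water):
        with pytest.raises(ValueError):
            scattering_vector(water, 660e-9, angle)


class TestSiegert:
    def test_unit_g1_case(self):
        cf = CorrelationFunction(lags=[1e-5], g2=[1.5], beta=0.5)
        g1, clipped = g1_from_g2(cf)
        assert g1[0] == pytest.approx(1.0)
        assert clipped == 0

    def test_baseline_maps_to_zero(self):
        cf = CorrelationFunction(lags=[1e-5, 1.0], g2=[1.5, 1.0], beta=0.5)
        g1, _ = g1_from_g2(cf)
        assert g1[1] == 0.0

    def test_negative_radicand_clipped_and_counted(self):
        cf = CorrelationFunction(lags=[1e-5, 1.0], g2=[1.5, 0.98], beta=0.5)
        g1, clipped = g1_from_g2(cf)
        assert g1[1] == 0.0
        assert clipped == 1

    def test_round_trip_with_generator(self, water, d_100nm):
        dls = DlsAcquisitionSpec(coherence_factor=0.8)
        cf = simulate_dls_g2([PopulationMode(rh=100e-9, number_density=1e10)], dls, water, seed=0)
        g1, _ = g1_from_g2(cf)
        q = scattering_vector(water)
        true_g1 = np.exp(-(q**2) * d_100nm * cf.lags)
        # the inverse is algebraically exact; in floats the error on g1 is
        # ~eps/(2 beta g1^2), so 1e-12 relative holds where g1 is not tiny
        keep = true_g1 > 0.05
        assert keep.sum() > 50
        np.testing.assert_allclose(g1[keep], true_g1[keep], rtol=1e-12)
        np.testing.assert_allclose(g1, true_g1, atol=1e-7)

    def test_beta_estimated_from_short_lag_limit(self, water):
        dls = DlsAcquisitionSpec(coherence_factor=0.63)
        cf = simulate_dls_g2([PopulationMode(rh=100e-9, number_density=1e10)], dls, water, seed=0)
        cf.beta = None
        assert estimate_beta(cf) == pytest.approx(0.63, rel=1e-3)

    def test_nonpositive_beta_rejected(self):
        cf = CorrelationFunction(lags=[1e-5], g2=[1.5])
        with pytest.raises(ValueError):
            g1_from_g2(cf, beta=0.0)


class TestInversion:
    def test_single_exponential_recovered_within_grid_spacing(self):
        gamma_true = 786.8
        g1 = np.exp(-gamma_true * LAGS)
        spec = invert_decay_spectrum(g1, LAGS, n_exponents=50, gamma_span=4.0)
        grid_ratio = spec.gamma_grid[1] / spec.gamma_grid[0]
        assert gamma_true / grid_ratio < spec.weighted_mean_gamma() < gamma_true * grid_ratio

    def test_two_equal_populations_gamma_ratio_16(self):
        g1 = 0.5 * np.exp(-100.0 * LAGS) + 0.5 * np.exp(-1600.0 * LAGS)
        spec = invert_decay_spectrum(g1, LAGS)
        dist = SizeDistribution(rh_grid=spec.gamma_grid, weights=spec.weights)  # rate axis
        peaks = peaks_from_distribution(dist)
        assert len(peaks) == 2
        for p in peaks:
            assert p.fraction == pytest.approx(0.5, abs=0.1)

    def test_flat_g1_puts_weight_in_slowest_bins(self):
        g1 = np.ones_like(LAGS)
        spec = invert_decay_spectrum(g1, LAGS)
        slowest_third = spec.weights[: len(spec.weights) // 3].sum()
        assert slowest_third > 0.99

    def test_matches_plain_nnls_oracle_at_zero_regularization(self):
        grid = default_gamma_grid(LAGS, 50, 6.0)
        assert np.any(np.isclose(grid, 786.8, rtol=0.2))
        g1 = np.exp(-786.8 * LAGS)
        spec = invert_decay_spectrum(g1, LAGS, reg_strength=0.0)
        A = np.exp(-np.outer(LAGS, grid))
        w_oracle, _ = nnls(A, g1)
        np.testing.assert_allclose(spec.weights, w_oracle / w_oracle.sum(), atol=1e-8)

    def test_total_variation_non_increasing_in_regularization(self):
        g1 = 0.5 * np.exp(-100.0 * LAGS) + 0.5 * np.exp(-1600.0 * LAGS)
        tvs = []
        for lam in [0.0, 1e-6, 1e-4, 1e-2, 1.0, 100.0]:
            spec = invert_decay_spectrum(g1, LAGS, reg_strength=lam)
            tvs.append(np.abs(np.diff(spec.weights)).sum())
        assert all(b <= a + 1e-8 for a, b in zip(tvs, tvs[1:]))

    def test_scaling_invariance_of_peak_positions(self):
        g1 = 0.5 * np.exp(-100.0 * LAGS) + 0.5 * np.exp(-1600.0 * LAGS)
        a = invert_decay_spectrum(g1, LAGS, reg_strength=1e-4)
        b = invert_decay_spectrum(3.7 * g1, LAGS, reg_strength=1e-4)
        ia = np.argsort(a.weights)[-2:]
        ib = np.argsort(b.weights)[-2:]
        assert set(ia) == set(ib)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            invert_decay_spectrum(np.zeros_like(LAGS), LAGS)
        with pytest.raises(ValueError):
            invert_decay_spectrum(np.exp(-LAGS), LAGS, n_exponents=51)

    def test_warns_when_underdetermined(self):
        lags = np.logspace(-5, -1, 30)
        with pytest.warns(UserWarning):
            invert_decay_spectrum(np.exp(-100 * lags), lags, n_exponents=50)


class TestSizeMapping:
    def test_rh_from_gamma_worked_chain(self, water):
        assert rh_from_gamma(786.8, 1.791e7, water) == pytest.approx(100e-9, rel=1e-3)

    def test_gamma_doubling_halves_rh(self, water):
        assert rh_from_gamma(200.0, 1.791e7, water) == pytest.approx(
            rh_from_gamma(100.0, 1.791e7, water) / 2, rel=1e-12
        )

    def test_nonpositive_inputs_rejected(self, water):
        with pytest.raises(ValueError):
            rh_from_gamma(0.0, 1.791e7, water)
        with pytest.raises(ValueError):
            rh_from_gamma(100.0, -1.0, water)

    def test_end_to_end_single_mode_recovery(self, water):
        dls = DlsAcquisitionSpec(coherence_factor=0.8)
        cf = simulate_dls_g2([PopulationMode(rh=100e-9, number_density=1e10)], dls, water, seed=0)
        res = DlsModel(cf, water).fit()
        assert len(res.peaks) == 1
        grid_ratio = res.distribution.rh_grid[1] / res.distribution.rh_grid[0]
        assert 100e-9 / grid_ratio < res.peaks[0].rh < 100e-9 * grid_ratio

    def test_fraction_invariants(self, water):
        dls = DlsAcquisitionSpec(coherence_factor=0.8)
        modes = [
            PopulationMode(rh=30e-9, number_density=3e10),
            PopulationMode(rh=120e-9, number_density=2e9),
            PopulationMode(rh=500e-9, number_density=2e6),
        ]
        cf = simulate_dls_g2(modes, dls, water, seed=0)
        res = DlsModel(cf, water).fit()
        total = sum(p.fraction for p in res.peaks)
        assert total <= 1 + 1e-9
        assert all(0 <= p.fraction <= 1 for p in res.peaks)
        assert [p.rh for p in res.peaks] == sorted(p.rh for p in res.peaks)


class TestPeaks:
    def test_single_peak_has_unit_fraction(self):
        grid = np.logspace(-9, -5, 40)
        w = np.zeros(40)
        w[10:13] = [0.2, 0.6, 0.2]
        peaks = peaks_from_distribution(SizeDistribution(rh_grid=grid, weights=w))
        assert len(peaks) == 1
        assert peaks[0].fraction == pytest.approx(1.0)

    def test_very_large_component_flagged(self):
        grid = np.logspace(-8, -4, 40)  # up to 100 um
        w = np.zeros(40)
        w[5] = 0.7
        w[-2] = 0.3  # far beyond 10 um
        peaks = peaks_from_distribution(SizeDistribution(rh_grid=grid, weights=w))
        assert peaks[-1].very_large
        assert not peaks[0].very_large

    def test_main_peak_convention_in_report_columns(self, water):
        dls = DlsAcquisitionSpec(coherence_factor=0.8)
        modes = [
            PopulationMode(rh=30e-9, number_density=3e10),
            PopulationMode(rh=120e-9, number_density=2e9),
        ]
        cf = simulate_dls_g2(modes, dls, water, seed=0)
        res = DlsModel(cf, water).fit()
        cols = res.peak_columns()
        assert cols["frac2"] == max(p.fraction for p in res.peaks)
        if cols["rh1_nm"] is not None:
            assert cols["rh1_nm"] < cols["rh2_nm"]
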