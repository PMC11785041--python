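import numpy as np
import pytest
from scipy.optimize import brentq

from sfxm import (ElementalMap, FitRanges, RadialProfile, SectorSpec,
                  analyze_map, analyze_profile, apply_wiener,
                  estimate_noise_floor, fit_signal, knee_frequency,
                  map_psd_profile, resolution, suggest_ranges, wiener_weights)
from sfxm.resolution import PowerLawFit

from conftest import brute_force_dft2


def make_profile(ur, s, sector=None):
    ur = np.asarray(ur, dtype=float)
    s = np.asarray(s, dtype=float)
    return RadialProfile(ur, s, np.ones_like(ur, dtype=int),
                         sector or SectorSpec())


def power_law_profile(P=10.0, a=-4.0, S_nf=0.0, n=40, lo=0.05, hi=0.5):
    ur = np.linspace(lo, hi, n)
    return make_profile(ur, P * ur**a + S_nf)


class TestFitRanges:
    @pytest.mark.parametrize("bad", [
        (0.2, 0.1, 0.3, 0.4),   # signal bounds reversed
        (0.1, 0.35, 0.3, 0.4),  # signal overlaps noise
        (0.1, 0.2, 0.4, 0.3),   # noise bounds reversed
    ])
    def test_ordering_enforced(self, bad):
        with pytest.raises(ValueError, match="fit ranges"):
            FitRanges(*bad)


class TestFitSignal:
    def test_exact_power_law_recovered_to_machine_precision(self):
        prof = power_law_profile(P=10.0, a=-4.0)
        P, a = fit_signal(prof, FitRanges(0.05, 0.5, 0.5, 1.0))
        np.testing.assert_allclose([P, a], [10.0, -4.0], rtol=1e-12)

    def test_two_points_define_the_line(self):
        prof = make_profile([0.1, 1.0], [1e4, 1.0])
        P, a = fit_signal(prof, FitRanges(0.05, 1.0, 1.0, 2.0))
        np.testing.assert_allclose([P, a], [1.0, -4.0], rtol=1e-12)

    def test_requires_two_usable_bins(self):
        prof = power_law_profile()
        with pytest.raises(ValueError, match="at least 2"):
            fit_signal(prof, FitRanges(0.001, 0.06, 0.5, 1.0))

    def test_rejects_non_positive_psd_values(self):
        prof = make_profile([0.1, 0.2, 0.3], [1.0, 0.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            fit_signal(prof, FitRanges(0.05, 0.35, 0.35, 0.5))

    def test_empty_bins_excluded(self):
        prof = power_law_profile(P=10.0, a=-4.0)
        prof.counts[5] = 0
        prof.S_values[5] = np.nan
        P, a = fit_signal(prof, FitRanges(0.05, 0.5, 0.5, 1.0))
        np.testing.assert_allclose([P, a], [10.0, -4.0], rtol=1e-12)


class TestNoiseFloor:
    @pytest.mark.parametrize("values, expected", [
        ([2.0, 2.0, 2.0], 2.0),
        ([1.0, 3.0], 2.0),
    ])
    def test_mean_of_noise_bins(self, values, expected):
        ur = np.linspace(0.5, 0.9, len(values))
        prof = make_profile(ur, values)
        assert estimate_noise_floor(
            prof, FitRanges(0.1, 0.3, 0.4, 1.0)) == expected

    def test_empty_noise_range_errors(self):
        prof = power_law_profile(hi=0.3)
        with pytest.raises(ValueError, match="noise range"):
            estimate_noise_floor(prof, FitRanges(0.05, 0.3, 0.5, 0.9))


class TestKneeAndResolution:
    def test_unit_ratio_gives_unit_knee(self):
        for a in (-1.0, -3.5, -6.0):
            assert knee_frequency(5.0, a, 5.0) == 1.0

    def test_direct_evaluation_example(self):
        # P u^a = S_nf with P=16, S_nf=1, a=-4 crosses at u=2
        np.testing.assert_allclose(knee_frequency(16.0, -4.0, 1.0), 2.0,
                                   rtol=1e-14)

    def test_agrees_with_bisection_root(self):
        for P in (0.5, 16.0, 1e4):
            for a in (-2.0, -3.5, -5.5):
                for S_nf in (0.1, 1.0, 300.0):
                    u = knee_frequency(P, a, S_nf)
                    root = brentq(lambda x: P * x**a - S_nf, 1e-8, 1e8,
                                  rtol=1e-15)
                    np.testing.assert_allclose(u, root, rtol=1e-10)

    @pytest.mark.parametrize("bad_call", [
        lambda: knee_frequency(1.0, 0.0, 1.0),
        lambda: knee_frequency(1.0, 0.5, 1.0),
        lambda: knee_frequency(-1.0, -4.0, 1.0),
        lambda: knee_frequency(1.0, -4.0, 0.0),
    ])
    def test_invalid_parameters_rejected(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()

    def test_snr_one_reduces_to_knee(self):
        u_res, delta = resolution(7.0, -3.5, 2.0, snr_res=1.0)
        assert u_res == knee_frequency(7.0, -3.5, 2.0)
        assert delta == 1.0 / (2.0 * u_res)

    def test_rose_criterion_example(self):
        u_res, delta = resolution(1.0, -4.0, 1.0, snr_res=5.0)
        np.testing.assert_allclose(u_res, 5.0 ** (-0.25), rtol=1e-14)
        np.testing.assert_allclose(delta, 0.5 * 5.0 ** 0.25, rtol=1e-14)

    def test_snr_below_one_rejected(self):
        with pytest.raises(ValueError, match="snr_res"):
            resolution(1.0, -4.0, 1.0, snr_res=0.5)

    def test_u_res_strictly_decreases_with_snr(self):
        u = [resolution(3.0, -3.5, 0.2, snr)[0] for snr in (1, 2, 5, 10, 50)]
        assert all(a > b for a, b in zip(u, u[1:]))


class TestWienerWeights:
    def test_half_at_signal_noise_crossing(self):
        P, a = 2.0, -3.0
        u_cross = knee_frequency(P, a, 5.0)
        w = wiener_weights(P, a, 5.0, np.array([u_cross]))
        np.testing.assert_allclose(w, 0.5, rtol=1e-12)

    def test_no_noise_limit_is_identity(self):
        w = wiener_weights(1.0, -4.0, 0.0, np.linspace(0.01, 1, 20))
        np.testing.assert_array_equal(w, 1.0)

    def test_direct_evaluation_example(self):
        w = wiener_weights(1.0, -4.0, 1.0, np.array([0.5]))
        np.testing.assert_allclose(w, 16.0 / 17.0, rtol=1e-12)

    def test_bounded_and_non_increasing(self):
        ur = np.linspace(0.0, 2.0, 200)
        w = wiener_weights(3.0, -3.5, 0.7, ur)
        assert np.all((w >= 0.0) & (w <= 1.0))
        assert np.all(np.diff(w) <= 1e-15)

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            wiener_weights(1.0, -4.0, -1.0, np.array([0.1]))


class TestApplyWiener:
    def _fit(self, P=1.0, a=-3.5, S_nf=0.0):
        return PowerLawFit(P=P, a=a, S_nf=S_nf, snr_res=5.0, u_knee=0.1,
                           u_res=0.05, delta_res=10.0,
                           ranges=FitRanges(0.01, 0.05, 0.2, 0.4))

    def test_zero_floor_is_identity(self, synthetic_map):
        out = apply_wiener(synthetic_map, self._fit(S_nf=0.0))
        np.testing.assert_allclose(out.values, synthetic_map.values,
                                   rtol=1e-9, atol=1e-9)

    def test_matches_brute_force_filter_oracle(self, rng):
        values = rng.poisson(50.0, size=(16, 16)).astype(float)
        values[0, 0] = -4.0  # exercise the offset path too
        emap = ElementalMap(values, dx=1.0, dy=2.0)
        fit = self._fit(P=2.0, a=-3.0, S_nf=40.0)
        out = apply_wiener(emap, fit)

        # oracle: brute-force DFT, explicit weights, brute-force inverse
        psi = np.sqrt(values + 4.0)
        F = brute_force_dft2(psi)
        ny, nx = psi.shape
        W = np.ones((ny, nx))
        for ky in range(ny):
            for kx in range(nx):
                uy = (ky if ky <= ny // 2 else ky - ny) / (ny * 2.0)
                ux = (kx if kx <= nx // 2 else kx - nx) / (nx * 1.0)
                ur = np.hypot(ux, uy)
                if ur > 0:
                    sig = fit.P * ur**fit.a
                    W[ky, kx] = sig / (sig + fit.S_nf)
        G = F * W
        psi_f = np.conj(brute_force_dft2(np.conj(G))) / (nx * ny)
        expected = psi_f.real**2 - 4.0
        np.testing.assert_allclose(out.values, expected, rtol=1e-8, atol=1e-8)

    def test_invalid_fit_rejected(self, synthetic_map):
        bad = self._fit()
        bad.a = 0.5
        bad.valid = False
        with pytest.raises(ValueError, match="invalid"):
            apply_wiener(synthetic_map, bad)

    def test_negatives_preserved_not_clipped(self):
        # a negative baseline forces offset 1; after filtering, background
        # pixels square to ~0 and the offset subtraction leaves them negative
        values = np.full((16, 16), -1.0)
        values[8, 8] = 100.0
        emap = ElementalMap(values, dx=1.0, dy=1.0)
        out = apply_wiener(emap, self._fit(P=2.0, a=-3.0, S_nf=100.0))
        assert out.values.min() < -0.5


class TestAnalyzeProfile:
    def test_invalid_when_slope_non_negative(self):
        ur = np.linspace(0.05, 0.5, 30)
        prof = make_profile(ur, 2.0 + ur)  # rising "signal"
        with pytest.warns(UserWarning, match="invalid"):
            fit = analyze_profile(prof, FitRanges(0.05, 0.3, 0.4, 0.5))
        assert not fit.valid
        assert np.isnan(fit.delta_res)

    def test_out_of_band_resolution_flagged(self):
        # floor so low the SNR=5 crossing lies beyond the band
        ur = np.linspace(0.05, 0.5, 40)
        s = np.where(ur <= 0.3, 1.0 * ur**-3.0, 1e-6)
        prof = make_profile(ur, s)
        with pytest.warns(UserWarning, match="optic-limited"):
            fit = analyze_profile(prof, FitRanges(0.05, 0.2, 0.45, 0.5))
        assert fit.out_of_band
        assert fit.u_res > 0.5

    def test_delta_res_is_half_period_of_u_res(self):
        prof = power_law_profile(P=5.0, a=-3.5, S_nf=10.0)
        fit = analyze_profile(prof, FitRanges(0.05, 0.15, 0.45, 0.5))
        assert fit.delta_res == 1.0 / (2.0 * fit.u_res)

    def test_scale_invariance_of_resolution(self, synthetic_map):
        ranges = FitRanges(0.01, 0.06, 0.3, 0.5)
        fit1 = analyze_profile(map_psd_profile(synthetic_map), ranges)
        c = 7.3
        fit2 = analyze_profile(map_psd_profile(synthetic_map.scaled(c)), ranges)
        np.testing.assert_allclose(fit2.P, c * fit1.P, rtol=1e-9)
        np.testing.assert_allclose(fit2.S_nf, c * fit1.S_nf, rtol=1e-9)
        np.testing.assert_allclose(
            [fit2.u_knee, fit2.u_res, fit2.delta_res],
            [fit1.u_knee, fit1.u_res, fit1.delta_res], rtol=1e-10)


class TestSuggestRanges:
    def test_heuristic_stays_below_knee_and_fits(self, synthetic_map):
        prof = map_psd_profile(synthetic_map)
        ranges = suggest_ranges(prof)
        fit = analyze_profile(prof, ranges)
        assert fit.valid
        assert ranges.signal_hi <= fit.u_knee  # fit region below the knee
        assert ranges.noise_hi == prof.occupied().ur_centers[-1]

    def test_analyze_map_defaults_to_heuristic(self, synthetic_map):
        fit = analyze_map(synthetic_map)
        assert fit.valid and fit.a < -2.0

    def test_featureless_profile_rejected(self):
        ur = np.linspace(0.05, 0.5, 30)
        prof = make_profile(ur, np.full_like(ur, 3.0))
        with pytest.raises(ValueError, match="noise floor"):
            suggest_ranges(prof)
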