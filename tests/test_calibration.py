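"""Calibration curves: extraction, OLS fit, LOD/LOQ, inversion, integration."""

import math

import numpy as np
import pytest

from cdquant import (
    CDSpectrum,
    Chromatogram,
    SignalExtractionRule,
    extract_signal,
    fit_calibration,
    integrate_peak,
    invert_calibration,
    lod_loq,
    make_calibration_series,
    simulate_cd,
    simulate_lc,
)
from cdquant.errors import (
    DegenerateDesignError,
    FlatResponseError,
    InsufficientDataError,
    InvalidParameterError,
    WindowRangeError,
)

# published five-point L-Leu calibration line, reused as ground truth
LEU_SLOPE, LEU_INTERCEPT = 0.1927, -0.53033
LEU_CONCS = [5.0, 10.0, 15.0, 20.0, 25.0]


def leu_line_points():
    return [(c, LEU_SLOPE * c + LEU_INTERCEPT) for c in LEU_CONCS]


class TestExtractSignal:
    def test_pure_l_positive_pure_d_mirror(self, leu):
        pure_l = simulate_cd(leu, 8.0, 0.0, noise_sd=0.0)
        pure_d = simulate_cd(leu, 0.0, 8.0, noise_sd=0.0)
        wl_l, th_l = extract_signal(pure_l)
        wl_d, th_d = extract_signal(pure_d)
        assert th_l > 0
        assert wl_d == wl_l
        assert th_d == -th_l

    def test_zero_spectrum_returns_first_window_point(self):
        lam = np.arange(185.0, 260.5, 0.5)
        spec = CDSpectrum(wavelengths=lam, theta=np.zeros_like(lam))
        wl, th = extract_signal(spec)
        assert (wl, th) == (190.0, 0.0)

    def test_tie_break_lowest_wavelength(self):
        lam = np.arange(185.0, 260.5, 0.5)
        theta = np.zeros_like(lam)
        theta[lam == 195.0] = 2.0
        theta[lam == 210.0] = -2.0  # same magnitude, higher wavelength
        spec = CDSpectrum(wavelengths=lam, theta=theta)
        assert extract_signal(spec) == (195.0, 2.0)

    def test_window_outside_grid(self):
        lam = np.arange(200.0, 230.5, 0.5)
        spec = CDSpectrum(wavelengths=lam, theta=np.zeros_like(lam))
        with pytest.raises(WindowRangeError):
            extract_signal(spec, SignalExtractionRule(window_lo=190.0, window_hi=220.0))

    def test_fixed_mode_nearest_point(self, leu):
        spec = simulate_cd(leu, 8.0, 0.0, noise_sd=0.0)
        rule = SignalExtractionRule(mode="fixed", wavelength=200.2)
        wl, th = extract_signal(spec, rule)
        assert wl == 200.0
        assert th == pytest.approx(spec.theta[spec.wavelengths == 200.0][0])

    def test_fixed_mode_outside_grid(self, leu):
        spec = simulate_cd(leu, 8.0, 0.0, noise_sd=0.0)
        with pytest.raises(WindowRangeError):
            extract_signal(spec, SignalExtractionRule(mode="fixed", wavelength=300.0))


class TestFitCalibration:
    def test_recovers_published_leu_line(self):
        curve = fit_calibration(leu_line_points(), "CD")
        assert curve.slope == pytest.approx(LEU_SLOPE, abs=1e-12)
        assert curve.intercept == pytest.approx(LEU_INTERCEPT, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert (curve.conc_lo, curve.conc_hi) == (5.0, 25.0)

    def test_collinear_three_points_two_levels(self):
        pts = [(1.0, 2.0), (1.0, 2.0), (3.0, 6.0)]
        curve = fit_calibration(pts, "CD")
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(2.0, abs=1e-12)

    def test_order_invariance(self):
        pts = leu_line_points()
        shuffled = [pts[3], pts[0], pts[4], pts[2], pts[1]]
        a, b = fit_calibration(pts, "CD"), fit_calibration(shuffled, "CD")
        assert (a.slope, a.intercept, a.r_squared) == (b.slope, b.intercept, b.r_squared)

    def test_error_conditions(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)], "CD")
        with pytest.raises(DegenerateDesignError):
            fit_calibration([(2.0, 1.0), (2.0, 1.1), (2.0, 0.9)], "CD")
        with pytest.raises(FlatResponseError):
            fit_calibration([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)], "CD")

    def test_noise_free_simulation_recovers_effective_slope(self, leu):
        """The fitted slope equals the simulator's peak response exactly."""
        series = make_calibration_series(leu, LEU_CONCS, noise_sd=0.0, seed=0)
        pts = [(c, extract_signal(s)[1]) for c, s in series]
        curve = fit_calibration(pts, "CD")
        unit = simulate_cd(leu, 1.0, 0.0, noise_sd=0.0)
        effective_slope = extract_signal(unit)[1]
        assert curve.slope == pytest.approx(effective_slope, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_slope_error_shrinks_with_series_length(self, leu):
        """Mean |slope error| decreases over n in {5, 20, 100} standards."""
        unit = simulate_cd(leu, 1.0, 0.0, noise_sd=0.0)
        effective_slope = extract_signal(unit)[1]
        mean_err = []
        for n in (5, 20, 100):
            concs = np.linspace(5.0, 25.0, n)
            errs = []
            for rep in range(30):
                series = make_calibration_series(
                    leu, concs, noise_sd=0.05, seed=1000 * n + rep
                )
                pts = [(c, extract_signal(s)[1]) for c, s in series]
                errs.append(abs(fit_calibration(pts, "CD").slope - effective_slope))
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]


class TestLodLoq:
    def test_formula(self):
        assert lod_loq(0.1, 1.0) == (pytest.approx(0.3), pytest.approx(1.0))
        assert lod_loq(0.0, 2.0) == (0.0, 0.0)

    @pytest.mark.parametrize("sd, slope", [(0.1, 1.0), (0.5, -0.2), (2.0, 7.0)])
    def test_fixed_ratio(self, sd, slope):
        lod, loq = lod_loq(sd, slope)
        assert loq / lod == pytest.approx(10.0 / 3.0)
        assert lod > 0

    def test_zero_slope(self):
        with pytest.raises(FlatResponseError):
            lod_loq(0.1, 0.0)
        with pytest.raises(InvalidParameterError):
            lod_loq(-0.1, 1.0)


class TestInvertCalibration:
    def test_published_line_inverse(self):
        curve = fit_calibration(leu_line_points(), "CD")
        signal = LEU_SLOPE * 13.0 + LEU_INTERCEPT
        conc, in_range = invert_calibration(curve, signal)
        assert conc == pytest.approx(13.00, abs=1e-9)
        assert in_range

    def test_signal_at_intercept_maps_to_zero(self):
        curve = fit_calibration(leu_line_points(), "CD")
        conc, in_range = invert_calibration(curve, curve.intercept)
        assert conc == pytest.approx(0.0, abs=1e-12)
        assert not in_range  # below both LOQ and working range

    @pytest.mark.parametrize("conc", [5.0, 9.3, 17.77, 25.0])
    def test_forward_inverse_identity(self, conc):
        curve = fit_calibration(leu_line_points(), "CD")
        back, in_range = invert_calibration(curve, curve.predict(conc))
        assert back == pytest.approx(conc, rel=1e-9)
        assert in_range

    def test_negative_signal_preserves_sign(self):
        """A D-excess (negative) signal inverts to a negative value."""
        pts = [(c, LEU_SLOPE * c) for c in LEU_CONCS]  # through origin
        curve = fit_calibration(pts, "CD")
        conc, _ = invert_calibration(curve, -LEU_SLOPE * 8.0)
        assert conc == pytest.approx(-8.0, rel=1e-9)


class TestIntegratePeak:
    def test_flat_zero_trace(self):
        t = np.linspace(0.0, 8.0, 1601)
        chrom = Chromatogram(times=t, absorbance=np.zeros_like(t))
        assert integrate_peak(chrom, 1.0, 7.0) == 0.0

    def test_gaussian_closed_form(self):
        t = np.linspace(0.0, 8.0, 4001)
        amp, mu, w = 40.0, 4.0, 0.12
        y = amp * np.exp(-0.5 * ((t - mu) / w) ** 2)
        area = integrate_peak(Chromatogram(times=t, absorbance=y), 3.0, 5.0)
        assert area == pytest.approx(amp * w * math.sqrt(2 * math.pi), rel=5e-3)

    def test_area_doubles_with_concentration(self, leu):
        a1 = integrate_peak(simulate_lc(leu, 6.0, noise_sd=0.0), 3.6, 4.8)
        a2 = integrate_peak(simulate_lc(leu, 12.0, noise_sd=0.0), 3.6, 4.8)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-9)

    def test_baseline_subtraction(self):
        t = np.linspace(0.0, 8.0, 1601)
        offset = 3.0
        y = offset + 10.0 * np.exp(-0.5 * ((t - 4.0) / 0.1) ** 2)
        chrom = Chromatogram(times=t, absorbance=y)
        raw = integrate_peak(chrom, 3.5, 4.5)
        corrected = integrate_peak(
            chrom, 3.5, 4.5, baseline_windows=[(0.5, 2.5), (6.0, 7.5)]
        )
        assert raw == pytest.approx(corrected + offset * 1.0, rel=1e-6)

    def test_window_errors(self, leu):
        chrom = simulate_lc(leu, 8.0, noise_sd=0.0)
        with pytest.raises(WindowRangeError):
            integrate_peak(chrom, 7.0, 9.0)
        with pytest.raises(InvalidParameterError):
            integrate_peak(chrom, 4.8, 3.6)
        with pytest.raises(WindowRangeError):
            integrate_peak(chrom, 1.0, 2.0, baseline_windows=[(8.5, 9.0)])
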