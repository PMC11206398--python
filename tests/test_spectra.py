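"""Broadened-spectrum construction, λmax extraction and shift analysis."""

import math

import numpy as np
import pytest

from tkispec import (
    GridMismatchError,
    NoQualifyingTransitionError,
    ValidationError,
    band_onset,
    broaden,
    difference_spectrum,
    lambda_max,
    peak_shift,
    provisional_peaks,
)
from tkispec.spectra import EV_NM

from conftest import make_stick


class TestBroaden:
    def test_single_stick_argmax_at_stick_position(self):
        spec = broaden(make_stick([(330.0, 0.5)]), grid=(300.0, 360.0, 0.1))
        assert abs(spec.argmax_nm() - 330.0) <= 0.1 + 1e-12

    def test_two_identical_sticks_double_the_spectrum(self):
        one = broaden(make_stick([(330.0, 0.5)]), grid=(300.0, 360.0, 0.5))
        two = broaden(
            make_stick([(330.0, 0.5), (330.0, 0.5)]), grid=(300.0, 360.0, 0.5)
        )
        np.testing.assert_allclose(two.absorbance, 2.0 * one.absorbance, rtol=1e-12)

    def test_linearity_of_superposition(self):
        grid = (200.0, 350.0, 0.2)
        s1 = make_stick([(330.0, 0.4), (250.0, 0.2)])
        s2 = make_stick([(280.0, 0.7)])
        s12 = make_stick([(330.0, 0.4), (250.0, 0.2), (280.0, 0.7)])
        np.testing.assert_allclose(
            broaden(s12, grid=grid).absorbance,
            broaden(s1, grid=grid).absorbance + broaden(s2, grid=grid).absorbance,
            rtol=1e-10,
        )

    def test_integrated_energy_intensity_proportional_to_total_f(self):
        # grid spans all sticks +/- 5 sigma, so areas scale as sum(f) to 1%
        grid = (150.0, 500.0, 0.05)
        single = broaden(make_stick([(300.0, 0.2)]), grid=grid)
        double = broaden(make_stick([(300.0, 0.2), (310.0, 0.3)]), grid=grid)
        ratio = double.integral_over_energy() / single.integral_over_energy()
        assert ratio == pytest.approx(0.5 / 0.2, rel=0.01)

    def test_shift_equivariance_in_energy(self):
        # displacing the single stick by delta_E moves the argmax accordingly
        grid = (250.0, 400.0, 0.05)
        base_nm = 320.0
        delta_e = 0.05  # eV
        shifted_nm = EV_NM / (EV_NM / base_nm + delta_e)
        a = broaden(make_stick([(base_nm, 0.5)]), grid=grid)
        b = broaden(make_stick([(shifted_nm, 0.5)]), grid=grid)
        assert abs((a.argmax_nm() - b.argmax_nm()) - (base_nm - shifted_nm)) <= 0.1

    def test_grid_excluding_all_sticks_warns_with_zero_spectrum(self):
        spec = broaden(make_stick([(330.0, 0.5)]), grid=(180.0, 200.0, 0.1))
        assert "warning" in spec.provenance
        assert np.max(spec.absorbance) < 1e-6 * 0.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            broaden(make_stick([(330.0, 0.5)]), fwhm_eV=0.0)
        with pytest.raises(ValidationError):
            broaden(make_stick([(330.0, 0.5)]), grid=(350.0, 180.0, 0.1))


class TestLambdaMax:
    def test_longest_wavelength_qualifying_state_wins(self):
        stick = make_stick([(326.71, 0.5295), (220.0, 0.9)])
        lam, f = lambda_max(stick, f_threshold=0.5, window=(320.0, 400.0))
        assert (lam, f) == (326.71, 0.5295)

    def test_single_qualifying_stick(self):
        assert lambda_max(make_stick([(330.0, 0.6)])) == (330.0, 0.6)

    def test_sub_threshold_states_raise_not_fall_back(self):
        stick = make_stick([(330.0, 0.49), (300.0, 0.3)])
        with pytest.raises(NoQualifyingTransitionError):
            lambda_max(stick, f_threshold=0.5)

    def test_wavelength_tie_broken_by_larger_f(self):
        stick = make_stick([(330.0, 0.55), (330.0, 0.65)])
        assert lambda_max(stick) == (330.0, 0.65)

    def test_window_excludes_strong_short_wavelength_bands(self):
        stick = make_stick([(220.0, 0.9), (330.0, 0.6)])
        assert lambda_max(stick, window=(320.0, 340.0))[0] == 330.0


class TestPeakShift:
    @pytest.mark.parametrize(
        "cal, crystal, sub, delta, cls",
        [
            (331.21, 333.17, "H", 1.96, "red"),
            (329.99, 326.71, "Br", -3.28, "blue"),
            (330.0, 330.0, "X", 0.0, "none"),
        ],
    )
    def test_delta_and_classification(self, cal, crystal, sub, delta, cls):
        rec = peak_shift(cal, crystal, sub)
        assert rec.delta_lambda_nm == pytest.approx(delta, abs=1e-9)
        assert rec.shift_class == cls

    def test_antisymmetry(self):
        a, b = 329.88, 327.54
        assert peak_shift(a, b).delta_lambda_nm == -peak_shift(b, a).delta_lambda_nm

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValidationError):
            peak_shift(0.0, 330.0)


class TestDifferenceSpectrum:
    def test_identical_spectra_give_zero_curve(self):
        s = broaden(make_stick([(330.0, 0.5)]), grid=(300.0, 360.0, 0.5))
        diff = difference_spectrum(s, s)
        np.testing.assert_allclose(diff.absorbance, 0.0, atol=1e-15)

    def test_difference_of_doubled_spectrum_recovers_original(self):
        grid = (300.0, 360.0, 0.5)
        s = broaden(make_stick([(330.0, 0.5)]), grid=grid)
        s2 = broaden(make_stick([(330.0, 0.5), (330.0, 0.5)]), grid=grid)
        np.testing.assert_allclose(
            difference_spectrum(s2, s).absorbance, s.absorbance, rtol=1e-12
        )

    def test_mismatched_grids_rejected(self):
        a = broaden(make_stick([(330.0, 0.5)]), grid=(300.0, 360.0, 0.5))
        b = broaden(make_stick([(330.0, 0.5)]), grid=(300.0, 360.0, 0.25))
        with pytest.raises(GridMismatchError):
            difference_spectrum(a, b)

    def test_extremum_location_matches_dense_grid_brute_force(self):
        # two single-stick spectra offset by 3 nm: locate the |difference|
        # extremum by brute-force scan at 0.01 nm and compare
        grid = (300.0, 360.0, 0.01)
        a = broaden(make_stick([(328.0, 0.5)]), grid=grid)
        b = broaden(make_stick([(331.0, 0.5)]), grid=grid)
        diff = difference_spectrum(a, b)
        idx = int(np.argmax(np.abs(diff.absorbance)))
        found = diff.wavelength_nm[idx]

        # independent brute force directly on the two-Gaussian energy model
        sigma = 0.333 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        wl = np.arange(300.0, 360.0, 0.01)
        e = EV_NM / wl
        model = np.exp(-0.5 * ((e - EV_NM / 328.0) / sigma) ** 2) - np.exp(
            -0.5 * ((e - EV_NM / 331.0) / sigma) ** 2
        )
        expected = wl[int(np.argmax(np.abs(model)))]
        assert found == pytest.approx(expected, abs=0.02)


class TestBandOnset:
    def test_onset_precedes_band_center(self):
        spec = broaden(make_stick([(330.0, 0.5)]), grid=(250.0, 400.0, 0.1))
        assert band_onset(spec) < 330.0

    def test_scale_invariance(self):
        spec = broaden(make_stick([(330.0, 0.5)]), grid=(250.0, 400.0, 0.1))
        doubled = type(spec)(spec.wavelength_nm, 2.0 * spec.absorbance, spec.provenance)
        assert band_onset(doubled) == band_onset(spec)

    def test_matches_analytic_gaussian_crossing(self):
        # for one Gaussian band the threshold crossing inverts in closed form:
        # E_onset = E0 + sigma * sqrt(2 ln(1/frac)), onset on the short-nm side
        frac, fwhm, center = 0.02, 0.333, 330.0
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        e_onset = EV_NM / center + sigma * math.sqrt(2.0 * math.log(1.0 / frac))
        expected_nm = EV_NM / e_onset
        step = 0.01
        spec = broaden(
            make_stick([(center, 0.5)]), fwhm_eV=fwhm, grid=(250.0, 400.0, step)
        )
        assert band_onset(spec, fraction_of_max=frac) == pytest.approx(
            expected_nm, abs=2 * step
        )

    def test_all_zero_spectrum_rejected(self):
        spec = broaden(make_stick([(330.0, 0.5)]), grid=(180.0, 200.0, 0.1))
        zero = type(spec)(spec.wavelength_nm, np.zeros_like(spec.absorbance))
        with pytest.raises(ValidationError):
            band_onset(zero)


def test_provisional_peaks_find_both_band_centers():
    spec = broaden(
        make_stick([(220.0, 0.5), (330.0, 0.5)]), grid=(180.0, 360.0, 0.1)
    )
    peaks = provisional_peaks(spec)
    assert any(abs(p - 220.0) < 0.5 for p in peaks)
    assert any(abs(p - 330.0) < 0.5 for p in peaks)
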