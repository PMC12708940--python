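import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimfret.errors import FitDegenerateError, InvalidInputError
from flimfret.photophysics import (ForsterParams, QuantumYieldInputs, Spectrum,
                                   TitrationSeries, find_peaks, fit_pka,
                                   forster_radius, overlap_integral,
                                   relative_quantum_yield,
                                   resample_to_common_grid)
from flimfret.synthetic import make_titration


class TestSpectrum:
    def test_rejects_non_monotonic_grid(self):
        with pytest.raises(InvalidInputError):
            Spectrum(np.array([500.0, 499.0, 501.0]), np.ones(3))

    def test_rejects_negative_extinction(self):
        with pytest.raises(InvalidInputError):
            Spectrum(np.array([500.0, 501.0]), np.array([1.0, -1.0]),
                     kind="extinction")


class TestResample:
    def test_identity_on_matching_grids(self):
        g = np.arange(500.0, 511.0, 1.0)
        a = Spectrum(g, g * 2.0)
        b = Spectrum(g, g * 3.0)
        ra, rb = resample_to_common_grid(a, b, 1.0)
        np.testing.assert_allclose(ra.wavelengths_nm, g)
        np.testing.assert_allclose(ra.values, a.values)
        np.testing.assert_allclose(rb.values, b.values)

    def test_range_intersection(self):
        a = Spectrum(np.arange(400.0, 701.0), np.ones(301))
        b = Spectrum(np.arange(500.0, 801.0), np.ones(301))
        ra, rb = resample_to_common_grid(a, b, 1.0)
        assert ra.wavelengths_nm[0] == 500.0
        assert ra.wavelengths_nm[-1] == 700.0
        assert ra.wavelengths_nm.size == 201

    def test_linear_interpolation_exact_on_affine_data(self):
        g = np.arange(400.0, 501.0, 2.0)
        a = Spectrum(g, g.copy())       # v(λ) = λ
        b = Spectrum(g, np.ones(g.size))
        ra, _ = resample_to_common_grid(a, b, 1.0)   # midpoints included
        np.testing.assert_allclose(ra.values, ra.wavelengths_nm, rtol=1e-14)

    def test_disjoint_ranges_give_empty_grids(self):
        a = Spectrum(np.array([400.0, 450.0]), np.ones(2))
        b = Spectrum(np.array([500.0, 550.0]), np.ones(2))
        ra, rb = resample_to_common_grid(a, b, 1.0)
        assert ra.wavelengths_nm.size == 0 and rb.wavelengths_nm.size == 0


class TestOverlapIntegral:
    def test_no_spectral_overlap_gives_zero(self):
        donor = Spectrum(np.arange(500.0, 551.0), np.ones(51), kind="emission")
        acceptor = Spectrum(np.arange(560.0, 611.0), np.full(51, 7e4),
                            kind="extinction")
        with pytest.warns(UserWarning):
            assert overlap_integral(donor, acceptor) == 0.0

    def test_narrow_band_limit_is_analytic(self):
        # unit-area triangle of half-width w centered at 600 nm against a
        # constant extinction: J -> eps * 600^4 as w -> 0
        w = 0.25
        g = np.array([600.0 - w, 600.0, 600.0 + w])
        donor = Spectrum(g, np.array([0.0, 1.0 / w, 0.0]), kind="emission")
        acceptor = Spectrum(np.array([550.0, 650.0]), np.array([72e3, 72e3]),
                            kind="extinction")
        j = overlap_integral(donor, acceptor, step_nm=0.005)
        assert j == pytest.approx(72e3 * 600.0 ** 4, rel=5e-6)

    def test_matches_fine_grid_oracle(self, mneongreen_spectra, mcherry_spectra):
        _, donor_em = mneongreen_spectra
        acc_ext, _ = mcherry_spectra
        j = overlap_integral(donor_em, acc_ext)
        fine = np.arange(420.0, 720.0, 0.01)
        d = np.interp(fine, donor_em.wavelengths_nm, donor_em.values)
        e = np.interp(fine, acc_ext.wavelengths_nm, acc_ext.values)
        d /= np.trapezoid(d, fine)
        j_oracle = np.trapezoid(d * e * fine ** 4, fine)
        assert j == pytest.approx(j_oracle, rel=1e-3)

    def test_invariant_to_donor_rescaling(self, mneongreen_spectra,
                                          mcherry_spectra):
        _, donor_em = mneongreen_spectra
        acc_ext, _ = mcherry_spectra
        scaled = Spectrum(donor_em.wavelengths_nm, donor_em.values * 137.0,
                          kind="emission")
        assert overlap_integral(scaled, acc_ext) == pytest.approx(
            overlap_integral(donor_em, acc_ext), rel=1e-12)

    def test_bilinear_in_extinction(self, mneongreen_spectra, mcherry_spectra):
        _, donor_em = mneongreen_spectra
        acc_ext, _ = mcherry_spectra
        doubled = Spectrum(acc_ext.wavelengths_nm, acc_ext.values * 2.0,
                           kind="extinction")
        assert overlap_integral(donor_em, doubled) == pytest.approx(
            2.0 * overlap_integral(donor_em, acc_ext), rel=1e-12)


class TestForsterRadius:
    def test_printed_worked_example(self):
        # J = 2.4e15 M^-1 cm^-1 nm^4, kappa2 = 2/3, Phi_D = 0.8, eta = 1.335
        r0 = forster_radius(ForsterParams(j=2.4e15))
        assert r0 == pytest.approx(57.1, rel=5e-3)

    def test_zero_overlap_gives_zero_radius(self):
        assert forster_radius(ForsterParams(j=0.0)) == 0.0

    def test_sixth_root_scaling(self):
        r1 = forster_radius(ForsterParams(j=1e15))
        r64 = forster_radius(ForsterParams(j=64e15))
        assert r64 == pytest.approx(2.0 * r1, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.05, 4.0), st.floats(0.05, 1.0), st.floats(1.0, 1.6),
           st.floats(1e13, 1e16))
    def test_sixth_power_proportional_to_j(self, kappa2, phi, eta, j):
        r0 = forster_radius(ForsterParams(kappa2=kappa2, phi_d=phi, eta=eta, j=j))
        assert r0 ** 6 == pytest.approx(
            0.2108 ** 6 * kappa2 * phi * eta ** -4 * j, rel=1e-9)


class TestQuantumYield:
    def test_identity_case(self):
        q = QuantumYieldInputs(i=5.0, a=0.05, i_ref=5.0, a_ref=0.05,
                               phi_ref=0.9, eta=1.33, eta_ref=1.33)
        assert relative_quantum_yield(q) == pytest.approx(0.9)

    def test_hand_computed_example(self):
        q = QuantumYieldInputs(i=1000.0, a=0.05, i_ref=1286.0, a_ref=0.05,
                               phi_ref=0.90, eta=1.335, eta_ref=1.330)
        expected = 0.9 * (1.335 / 1.330) ** 2 * (1000.0 / 1286.0)
        assert relative_quantum_yield(q) == pytest.approx(expected, rel=1e-12)
        assert relative_quantum_yield(q) == pytest.approx(0.705, abs=5e-3)

    def test_ratio_invariance(self):
        q1 = QuantumYieldInputs(i=1000.0, a=0.05, i_ref=1286.0, a_ref=0.05,
                                phi_ref=0.90)
        q2 = QuantumYieldInputs(i=2000.0, a=0.10, i_ref=643.0, a_ref=0.025,
                                phi_ref=0.90)
        assert relative_quantum_yield(q1) == pytest.approx(
            relative_quantum_yield(q2), rel=1e-12)

    def test_zero_absorbance_rejected(self):
        with pytest.raises(InvalidInputError):
            QuantumYieldInputs(i=1.0, a=0.0, i_ref=1.0, a_ref=0.05, phi_ref=0.9)


class TestPkaFit:
    def test_recovery_at_one_percent_noise(self):
        series, truth = make_titration(5.9, 1.0, 0.02, 1.0,
                                       np.linspace(3.5, 8.5, 10),
                                       noise=0.01, replicates=3, seed=0)
        fit = fit_pka(series)
        assert fit.pka == pytest.approx(truth["pka"], abs=0.1)

    def test_noiseless_exact_recovery(self):
        series, _ = make_titration(6.2, 1.0, 0.0, 1.0, np.linspace(4.0, 9.0, 10),
                                   noise=0.0, replicates=1, seed=0)
        fit = fit_pka(series)
        assert fit.pka == pytest.approx(6.2, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-4)

    def test_flat_series_is_degenerate(self):
        t = TitrationSeries(np.linspace(3.0, 9.0, 8), np.full(8, 0.5))
        with pytest.raises(FitDegenerateError):
            fit_pka(t)

    def test_too_few_points_rejected(self):
        t = TitrationSeries(np.array([4.0, 5.0, 6.0, 7.0]),
                            np.array([0.1, 0.3, 0.7, 0.9]))
        with pytest.raises(InvalidInputError):
            fit_pka(t)


class TestFindPeaks:
    def test_mneongreen_absorption_peak(self, mneongreen_spectra):
        absorption, emission = mneongreen_spectra
        assert find_peaks(absorption)["peaks"][0][0] == pytest.approx(506.0, abs=1.0)
        assert find_peaks(emission)["peaks"][0][0] == pytest.approx(520.0, abs=1.0)

    def test_monotone_spectrum_flags_endpoint(self):
        g = np.arange(500.0, 521.0)
        s = Spectrum(g, np.linspace(0.0, 1.0, g.size))
        res = find_peaks(s)
        assert res["peaks"] == []
        assert res["endpoint_maxima"] == [(520.0, 1.0)]

    def test_two_gaussian_modes_recovered(self):
        g = np.arange(450.0, 701.0, 1.0)
        v = np.exp(-0.5 * ((g - 520.0) / 10) ** 2) + \
            0.8 * np.exp(-0.5 * ((g - 607.0) / 12) ** 2)
        peaks = find_peaks(Spectrum(g, v))["peaks"]
        got = sorted(p[0] for p in peaks[:2])
        assert got[0] == pytest.approx(520.0, abs=1.0)
        assert got[1] == pytest.approx(607.0, abs=1.0)
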