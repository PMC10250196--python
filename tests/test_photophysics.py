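import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gecilab import photophysics as pp
from gecilab import synthetic_data as sd
from gecilab.errors import (
    DegenerateRegressionError,
    FitQualityWarning,
    MissingReferenceError,
    SignError,
    WindowCoverageError,
)

from conftest import make_band_spectrum, make_series


class TestBandAmplitudes:
    def test_zero_spectrum(self):
        wl = np.arange(360.0, 660.0, 1.0)
        s = pp.AbsorbanceSpectrum(wl, np.zeros_like(wl), 7.0)
        assert pp.band_amplitudes(s) == (0.0, 0.0)

    def test_two_gaussian_bands(self):
        # oracle: the generating Gaussian amplitudes; cross-band bleed at
        # the window maxima is < 1e-3 at these widths
        s = make_band_spectrum(0.30, 0.60, 7.0)
        od_n, od_a = pp.band_amplitudes(s, smooth=False)
        assert od_n == pytest.approx(0.30, abs=1e-3)
        assert od_a == pytest.approx(0.60, abs=1e-3)
        # median-filter smoothing perturbs the peak by < 0.5%
        od_n_s, od_a_s = pp.band_amplitudes(s)
        assert od_n_s == pytest.approx(0.30, rel=5e-3)
        assert od_a_s == pytest.approx(0.60, rel=5e-3)

    def test_single_anionic_band(self):
        s = make_band_spectrum(0.0, 0.5, 7.0)
        od_n, od_a = pp.band_amplitudes(s)
        assert od_a == pytest.approx(0.5, rel=5e-3)
        assert od_n < 0.01

    def test_window_not_covered(self):
        wl = np.arange(450.0, 660.0, 1.0)
        s = pp.AbsorbanceSpectrum(wl, np.zeros_like(wl), 7.0)
        with pytest.raises(WindowCoverageError):
            pp.band_amplitudes(s)

    def test_baseline_subtraction(self):
        s = make_band_spectrum(0.0, 0.5, 7.0)
        s.absorbance = s.absorbance + 0.07  # turbidity offset
        _, od_a = pp.band_amplitudes(s)
        assert od_a == pytest.approx(0.5, rel=5e-3)


class TestTitrationSlope:
    def test_exact_line(self):
        series = make_series([(0.1, 0.9), (0.2, 0.8), (0.3, 0.7)])
        fit = pp.titration_slope(series, smooth=False)
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)

    def test_conservation_generated_ratio(self):
        # OD_A = const - 3 OD_N follows from n_A + n_N = const with
        # eps_A/eps_N = 3
        series = make_series([(0.10, 0.90), (0.15, 0.75), (0.25, 0.45)])
        fit = pp.titration_slope(series, smooth=False)
        assert fit.slope == pytest.approx(-3.0, abs=1e-9)

    def test_duplicated_point_leaves_slope(self):
        a = make_series([(0.1, 0.9), (0.2, 0.8), (0.3, 0.7)])
        b = make_series([(0.1, 0.9), (0.2, 0.8), (0.3, 0.7), (0.3, 0.7)])
        assert (pp.titration_slope(b, smooth=False).slope
                == pytest.approx(pp.titration_slope(a, smooth=False).slope))

    def test_constant_od_n_degenerate(self):
        series = make_series([(0.2, 0.9), (0.2, 0.8), (0.2, 0.7)])
        with pytest.raises(DegenerateRegressionError):
            pp.titration_slope(series, smooth=False)


class TestExtinctionCoefficients:
    @pytest.mark.parametrize("eps_a", [64_260.0, 220.0],
                             ids=["ca_saturated", "ca_free"])
    def test_round_trip_recovery(self, eps_a):
        series, truth = sd.gen_ph_spectra(sd.ChromophoreConfig(eps_a=eps_a))
        params = pp.extinction_coefficients(series, eval_ph=7.2)
        assert params.eps_a == pytest.approx(eps_a, rel=1e-3)
        assert params.eps_n == pytest.approx(truth.eps_n, rel=1e-3)
        assert params.rho_a + params.rho_n == pytest.approx(1.0, abs=1e-9)

    def test_fully_anionic_series_degenerate(self):
        series = make_series([(0.0, 0.8), (0.0, 0.8), (0.0, 0.8)])
        with pytest.raises(DegenerateRegressionError):
            pp.extinction_coefficients(series)

    def test_positive_slope_rejected(self):
        series = make_series([(0.1, 0.2), (0.2, 0.4), (0.3, 0.6)])
        with pytest.raises(SignError):
            pp.extinction_coefficients(series)

    @given(eps_a=st.floats(1e3, 1e5), ratio=st.floats(1.5, 10.0),
           pka=st.floats(6.5, 8.5), conc=st.floats(1.0, 10.0),
           noise=st.floats(0.0, 0.02))
    @settings(max_examples=25, deadline=None)
    def test_chromophore_conservation(self, eps_a, ratio, pka, conc, noise):
        # OD_D/eps_D = OD_A/eps_A + OD_N/eps_N to 1e-9 relative, even on
        # noisy series: the inversion enforces it by construction
        cfg = sd.ChromophoreConfig(eps_a=eps_a, eps_n=eps_a / ratio, pka=pka,
                                   concentration_uM=conc, noise_cv=noise,
                                   seed=7)
        series, _ = sd.gen_ph_spectra(cfg)
        params = pp.extinction_coefficients(series, eval_ph=7.2)
        od_n, od_a = pp.band_amplitudes(series.at_ph(7.2))
        od_d = pp.peak_od(series.denatured, (380.0, 540.0))
        lhs = od_d / params.eps_d
        rhs = od_a / params.eps_a + od_n / params.eps_n
        assert rhs == pytest.approx(lhs, rel=1e-9)

    def test_slope_negative_whenever_protonation_varies(self):
        for seed in range(5):
            cfg = sd.ChromophoreConfig(seed=seed, noise_cv=0.01)
            series, _ = sd.gen_ph_spectra(cfg)
            assert pp.titration_slope(series).slope < 0


class TestPka:
    def test_exact_sigmoid(self):
        ph = np.array([6.5, 7.0, 7.5, 8.0, 8.5])
        rho = 1.0 / (1.0 + 10.0 ** (7.5 - ph))
        fit = pp.fit_pka(ph, rho)
        assert fit.pka == pytest.approx(7.5, abs=1e-6)
        assert fit.h == pytest.approx(1.0, abs=1e-6)

    def test_flat_fraction_warns(self):
        ph = np.array([6.5, 7.0, 7.5, 8.0])
        with pytest.warns(FitQualityWarning):
            fit = pp.fit_pka(ph, np.ones_like(ph))
        assert np.isnan(fit.pka)

    def test_hill_coefficient_recovery(self):
        ph = np.linspace(5.5, 8.5, 9)
        rho = 1.0 / (1.0 + 10.0 ** (2.0 * (7.0 - ph)))
        fit = pp.fit_pka(ph, rho)
        assert fit.pka == pytest.approx(7.0, abs=1e-4)
        assert fit.h == pytest.approx(2.0, abs=1e-4)

    def test_pka_recovered_through_full_pipeline(self):
        series, _ = sd.gen_ph_spectra(sd.ChromophoreConfig(pka=7.3, h=1.0))
        params = pp.extinction_coefficients(series)
        assert params.pka == pytest.approx(7.3, abs=1e-3)


class TestQuantumYield:
    def test_equal_slopes_fluorescein(self):
        pts = np.array([[0.01, 10.0], [0.02, 20.0], [0.04, 40.0]])
        data = pp.QuantumYieldData(pts, standard_slope=1000.0,
                                   standard_phi=0.925)
        assert pp.quantum_yield(data).phi == pytest.approx(0.925, abs=1e-12)

    def test_half_slope_tolles(self):
        pts = np.array([[0.01, 5.0], [0.02, 10.0]])
        data = pp.QuantumYieldData(pts, standard_slope=1000.0,
                                   standard_phi=0.79)
        assert pp.quantum_yield(data).phi == pytest.approx(0.395, abs=1e-12)

    def test_zero_absorbance_degenerate(self):
        pts = np.array([[0.0, 5.0], [0.0, 10.0]])
        with pytest.raises(DegenerateRegressionError):
            pp.quantum_yield(pp.QuantumYieldData(pts, standard_slope=1.0))

    def test_above_unity_yield_warns(self):
        pts = np.array([[0.01, 20.0], [0.02, 40.0]])
        data = pp.QuantumYieldData(pts, standard_slope=1000.0,
                                   standard_phi=0.925)
        with pytest.warns(FitQualityWarning):
            res = pp.quantum_yield(data)
        assert res.phi == pytest.approx(1.85)


class TestTwoPhoton:
    def _point(self, **kw):
        base = dict(wavelength_nm=920.0, f_sample=1.0, f_standard=1.0,
                    c_sample=1e-6, c_standard=1e-6, eta2_sample=0.925,
                    eta2_standard=0.925, delta_standard=13.0)
        base.update(kw)
        return pp.TwoPhotonPoint(**base)

    def test_identity(self):
        assert pp.two_photon_cross_section(self._point()) == pytest.approx(13.0)

    def test_linearity_in_sample_flux(self):
        assert (pp.two_photon_cross_section(self._point(f_sample=2.0))
                == pytest.approx(26.0))

    @given(g=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity(self, g):
        # degree +1 in the sample flux, -1 in the standard flux
        d0 = pp.two_photon_cross_section(self._point())
        assert (pp.two_photon_cross_section(self._point(f_sample=g))
                == pytest.approx(g * d0))
        assert (pp.two_photon_cross_section(self._point(f_standard=g))
                == pytest.approx(d0 / g))

    def test_bundled_fluorescein_reference(self):
        p = self._point(delta_standard=None)
        expected = pp.fluorescein_cross_section(920.0)
        assert pp.two_photon_cross_section(p) == pytest.approx(expected)

    def test_outside_reference_range(self):
        with pytest.raises(MissingReferenceError):
            pp.two_photon_cross_section(self._point(wavelength_nm=700.0,
                                                    delta_standard=None))
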