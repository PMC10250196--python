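import numpy as np
import pytest

from gecilab import ipeaq as ip
from gecilab import synthetic_data as sd
from gecilab.calcium_titration import HillFit
from gecilab.errors import (
    CalibrationRangeError,
    NoCycleError,
    OrientationError,
    UnidentifiableFitError,
)


def square_wave_trace(f_on=1.2, f_off=1.0, n_cycles=3, hz=20.0,
                      violet_s=2.5, gap_s=4.0):
    period = violet_s + gap_s
    t = np.arange(0.0, n_cycles * period + gap_s, 1.0 / hz)
    violet = np.zeros(t.size, dtype=bool)
    f = np.full(t.size, f_off)
    for k in range(n_cycles):
        on = k * period
        m = (t >= on) & (t < on + violet_s)
        violet[m] = True
        f[m] = f_on
    return ip.PhotochromicTrace(t, f, violet)


class TestDetectCycles:
    def test_square_wave_contrast(self):
        cycles = ip.detect_cycles(square_wave_trace(1.2, 1.0))
        assert len(cycles) == 3
        for c in cycles:
            assert c.contrast == pytest.approx(1.0 / 6.0)

    def test_no_photochromism_zero_contrast(self):
        cycles = ip.detect_cycles(square_wave_trace(1.0, 1.0))
        assert all(c.contrast == pytest.approx(0.0) for c in cycles)

    def test_generator_contrast_recovery(self):
        # relaxation tau 0.5 s with 4-s gaps (>= 5 tau): mean contrast
        # within 1% of the generating value
        cfg = sd.PhotochromicConfig(contrast_c0=0.40, contrast_cinf=0.40,
                                    n_cycles=5)
        trace, truth = sd.gen_photochromic(cfg, ca_truth=100.0)
        cycles = ip.detect_cycles(trace)
        mean_c = np.mean([c.contrast for c in cycles])
        assert mean_c == pytest.approx(0.40, rel=0.01)

    def test_no_violet_epoch(self):
        t = np.arange(0.0, 10.0, 0.05)
        trace = ip.PhotochromicTrace(t, np.ones(t.size),
                                     np.zeros(t.size, dtype=bool))
        with pytest.raises(NoCycleError):
            ip.detect_cycles(trace)

    def test_extrema_method_matches_on_square_wave(self):
        trace = square_wave_trace(1.5, 1.0)
        for method in ("plateau", "extrema"):
            c = ip.detect_cycles(trace, method=method)[0]
            assert c.contrast == pytest.approx(1.0 / 3.0)


class TestCalibrations:
    def test_noiseless_parameter_recovery(self):
        cfg = sd.PhotochromicConfig()
        ca, contrast, fluor = sd.gen_calibration_tables(cfg, n_points=14)
        cal = ip.fit_calibrations(ca, contrast, ca, fluor)
        assert cal.contrast_curve.kd == pytest.approx(cfg.contrast_kd_nM,
                                                      rel=1e-4)
        assert cal.fluor_curve.kd == pytest.approx(cfg.fluor_kd_nM, rel=1e-4)
        assert cal.contrast_curve.f_min == pytest.approx(cfg.contrast_c0,
                                                         rel=1e-4)
        assert cal.fluor_curve.f_max == pytest.approx(cfg.fluor_f_max,
                                                      rel=1e-4)

    def test_constant_contrast_unidentifiable(self):
        ca = np.logspace(0, 4, 8)
        with pytest.raises(UnidentifiableFitError):
            ip.fit_calibrations(ca, np.full(8, 0.4), ca,
                                1 + 100 * ca / (ca + 200))

    def test_increasing_contrast_rejected(self):
        ca = np.logspace(0, 4, 10)
        rising = 0.1 + 0.6 * ca / (ca + 200.0)
        with pytest.raises(OrientationError):
            ip.fit_calibrations(ca, rising, ca, 1 + 100 * ca / (ca + 200))

    def test_json_round_trip(self):
        cal = sd.PhotochromicConfig().calibration()
        cal2 = ip.IPEAQCalibration.from_json(cal.to_json())
        assert cal2.contrast_curve.kd == cal.contrast_curve.kd
        assert cal2.fluor_curve.h == cal.fluor_curve.h


class TestHillInverse:
    def test_round_trip(self):
        fit = HillFit(1.0, 103.3, 200.0, 2.0)
        ca = np.logspace(0.5, 3.5, 25)
        assert np.allclose(ip.hill_inverse(fit, fit(ca)), ca, rtol=1e-10)

    def test_decreasing_curve_round_trip(self):
        fit = HillFit(0.75, 0.05, 250.0, 1.0)
        ca = np.logspace(0.5, 3.5, 25)
        assert np.allclose(ip.hill_inverse(fit, fit(ca)), ca, rtol=1e-10)

    def test_out_of_range_raises_without_clip(self):
        fit = HillFit(1.0, 100.0, 200.0, 2.0)
        with pytest.raises(CalibrationRangeError):
            ip.hill_inverse(fit, 101.0)

    def test_clip_flags(self):
        fit = HillFit(1.0, 100.0, 200.0, 2.0)
        ca, oor = ip.hill_inverse(fit, np.array([50.0, 101.0]), clip=True)
        assert list(oor) == [False, True]
        assert np.all(np.isfinite(ca))


class TestQuantify:
    @staticmethod
    def _release(t):
        return sd.cch_transient(t, 100.0, 1000.0, t_on_s=35.0)

    def test_fixed_point_constant_trace(self):
        cfg = sd.PhotochromicConfig()
        trace, truth = sd.gen_photochromic(cfg, ca_truth=200.0,
                                           duration_s=40.0)
        q = ip.quantify(trace, truth["calibration"])
        assert q.basal_ca_nM == pytest.approx(200.0, rel=0.01)
        assert q.norm_factor == pytest.approx(1.0, rel=0.01)
        valid = np.isfinite(q.ca_nM)
        assert np.allclose(q.ca_nM[valid], 200.0, rtol=0.01)

    def test_round_trip_noiseless(self):
        cfg = sd.PhotochromicConfig()
        trace, truth = sd.gen_photochromic(cfg, self._release,
                                           duration_s=60.0)
        q = ip.quantify(trace, truth["calibration"])
        valid = np.isfinite(q.ca_nM)
        rel = np.abs(q.ca_nM[valid] - truth["ca_nM"][valid]) / truth["ca_nM"][valid]
        assert rel.max() < 0.01

    def test_gain_invariance(self):
        # the property that makes the readout absolute: any detector gain
        # is absorbed by the normalizing factor
        cfg = sd.PhotochromicConfig(noise_cv=0.01, seed=5)
        trace, truth = sd.gen_photochromic(cfg, self._release,
                                           duration_s=60.0)
        q1 = ip.quantify(trace, truth["calibration"])
        scaled = ip.PhotochromicTrace(trace.time_s, 123.4 * trace.f,
                                      trace.violet_on)
        q2 = ip.quantify(scaled, truth["calibration"])
        assert np.nanmax(np.abs(q2.ca_nM - q1.ca_nM)
                         / np.abs(q1.ca_nM)) < 1e-9

    def test_contrast_invariant_to_units(self):
        trace = square_wave_trace(1.2, 1.0)
        scaled = ip.PhotochromicTrace(trace.time_s, 50.0 * trace.f,
                                      trace.violet_on)
        c1 = [c.contrast for c in ip.detect_cycles(trace)]
        c2 = [c.contrast for c in ip.detect_cycles(scaled)]
        assert np.allclose(c1, c2)

    def test_basal_at_plateau_out_of_calibration(self):
        # zero-photochromism trace: contrast 0 sits below the
        # Ca-saturated plateau of the contrast calibration
        cfg = sd.PhotochromicConfig()
        trace = square_wave_trace(1.0, 1.0)
        with pytest.raises(CalibrationRangeError):
            ip.quantify(trace, cfg.calibration())
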