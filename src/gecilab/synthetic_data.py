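"""Synthetic measurement generators with known ground truth.

Every input consumed by the analysis modules can be generated here with
a fixed seed: two-band protonation spectra across a pH series, Hill
titrations, single-exponential off-rate traces, photochromic cycle
traces, action-potential-train fluorescence transients, and
trial-structured drifting-grating tuning tables.  Fluorescence noise is
multiplicative Gaussian parameterized by a coefficient of variation
(shot-noise-dominated imaging); tuning-table noise is additive on the
dF/F0 scale.  Each generator returns its ground truth alongside the
data so estimators can be tested by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .calcium_titration import HillFit, KineticTrace, TitrationCurve, hill_curve
from .errors import ConfigError, OrientationError
from .ipeaq import IPEAQCalibration, PhotochromicTrace
from .photophysics import AbsorbanceSpectrum, ChromophoreParams, PHSeries
from .trace_analysis import FluorescenceTrace

__all__ = [
    "ChromophoreConfig",
    "TitrationConfig",
    "KineticConfig",
    "PhotochromicConfig",
    "APTrainConfig",
    "TuningConfig",
    "gen_ph_spectra",
    "gen_titration",
    "gen_kinetic",
    "gen_photochromic",
    "gen_calibration_tables",
    "gen_ap_train",
    "gen_tuning",
    "cch_transient",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _mult_noise(values: np.ndarray, cv: float,
                rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return values
    return values * (1.0 + cv * rng.standard_normal(values.shape))


# --------------------------------------------------------------------------
# pH-titration absorbance spectra

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ChromophoreConfig:
    """Two-state chromophore forward model for a pH titration.

    Extinction coefficients in M-1 cm-1; the defaults are the
    Ca2+-saturated high-contrast sensor values (anionic 64,260) with a
    neutral state of 21,420 and pKa 7.0.  Absorption bands are Gaussian
    in wavelength with the given full width at half maximum; the
    denatured chromophore absorbs at 447 nm with eps 44,000.
    """

    eps_a: float = 64_260.0
    eps_n: float = 21_420.0
    pka: float = 7.0
    h: float = 1.0
    concentration_uM: float = 4.0
    center_n_nm: float = 403.0
    center_a_nm: float = 509.0
    center_d_nm: float = 447.0
    fwhm_nm: float = 25.0
    eps_d: float = 44_000.0
    ph_values: tuple = (7.0, 7.2, 8.0, 9.0)
    denatured_ph: float = 12.5
    ca_state: str = "ca_saturated"
    grid_nm: tuple = (360.0, 660.0, 1.0)  # start, stop, step
    noise_cv: float = 0.0
    seed: int = 0


def _gauss(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def gen_ph_spectra(cfg: ChromophoreConfig) -> tuple[PHSeries, ChromophoreParams]:
    """Forward-simulate a pH series; returns (series, ground truth).

    State populations follow the Henderson-Hasselbalch sigmoid
    rho_A = 1/(1 + 10^(h (pKa - pH))); each spectrum is the sum of the
    neutral and anionic Gaussian bands weighted by eps * population;
    the denatured spectrum carries the full chromophore amount in a
    single band.  Ground-truth state fractions refer to pH 7.2.
    """
    # native band separation must dominate: reject configs whose bands
    # overlap by more than 10% energy (Bhattacharyya coefficient)
    sigma = cfg.fwhm_nm * _FWHM_TO_SIGMA
    d = abs(cfg.center_a_nm - cfg.center_n_nm)
    if np.exp(-(d ** 2) / (8.0 * sigma ** 2)) > 0.10:
        raise ConfigError("neutral/anionic bands overlap beyond 10% energy")

    rng = _rng(cfg.seed)
    wl = np.arange(*cfg.grid_nm)
    n_total = cfg.concentration_uM * 1e-6
    spectra = []
    for ph in cfg.ph_values:
        rho_a = 1.0 / (1.0 + 10.0 ** (cfg.h * (cfg.pka - ph)))
        od = (cfg.eps_n * n_total * (1 - rho_a) * _gauss(wl, cfg.center_n_nm, cfg.fwhm_nm)
              + cfg.eps_a * n_total * rho_a * _gauss(wl, cfg.center_a_nm, cfg.fwhm_nm))
        spectra.append(AbsorbanceSpectrum(
            wl, _mult_noise(od, cfg.noise_cv, rng), ph, cfg.ca_state))
    od_d = cfg.eps_d * n_total * _gauss(wl, cfg.center_d_nm, cfg.fwhm_nm)
    spectra.append(AbsorbanceSpectrum(
        wl, _mult_noise(od_d, cfg.noise_cv, rng), cfg.denatured_ph, cfg.ca_state))

    rho_ref = 1.0 / (1.0 + 10.0 ** (cfg.h * (cfg.pka - 7.2)))
    truth = ChromophoreParams(
        slope_s=-cfg.eps_a / cfg.eps_n, eps_n=cfg.eps_n, eps_a=cfg.eps_a,
        rho_a=rho_ref, rho_n=1.0 - rho_ref, pka=cfg.pka, eps_d=cfg.eps_d)
    return PHSeries(spectra), truth


# --------------------------------------------------------------------------
# Hill titrations and off-rate kinetics

@dataclass
class TitrationConfig:
    """Forward Hill dose-response; concentrations log-spaced around kd."""

    f_min: float = 1.0
    f_max: float = 103.3
    kd_nM: float = 200.0
    h: float = 2.0
    n_points: int = 12
    span_decades: float = 2.0  # each side of kd
    noise_cv: float = 0.0
    seed: int = 0


def gen_titration(cfg: TitrationConfig) -> tuple[TitrationCurve, HillFit]:
    if cfg.n_points < 5:
        raise ConfigError("need >= 5 concentrations")
    rng = _rng(cfg.seed)
    ca = np.logspace(np.log10(cfg.kd_nM) - cfg.span_decades,
                     np.log10(cfg.kd_nM) + cfg.span_decades, cfg.n_points)
    f = hill_curve(ca, cfg.f_min, cfg.f_max, cfg.kd_nM, cfg.h)
    truth = HillFit(cfg.f_min, cfg.f_max, cfg.kd_nM, cfg.h)
    return TitrationCurve(ca, _mult_noise(f, cfg.noise_cv, rng)), truth


@dataclass
class KineticConfig:
    """Single-exponential Ca2+-removal decay."""

    koff: float = 2.0        # s^-1
    plateau: float = 1.0
    amplitude: float = 5.0
    duration_efolds: float = 6.0
    sampling_hz: float = 200.0
    noise_cv: float = 0.0
    seed: int = 0


def gen_kinetic(cfg: KineticConfig) -> tuple[KineticTrace, dict]:
    rng = _rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_efolds / cfg.koff, 1.0 / cfg.sampling_hz)
    f = cfg.plateau + cfg.amplitude * np.exp(-cfg.koff * t)
    truth = {"koff": cfg.koff, "plateau": cfg.plateau,
             "amplitude": cfg.amplitude}
    return KineticTrace(t, _mult_noise(f, cfg.noise_cv, rng)), truth


# --------------------------------------------------------------------------
# Photochromic cycles

@dataclass
class PhotochromicConfig:
    """Photochromic-cycle forward model with its two Hill calibrations.

    The fluorescence calibration (increasing) and photochromism-contrast
    calibration (decreasing) share the [Ca2+] axis in nM.  Violet
    epochs raise the fluorescence instantaneously so that the cycle
    contrast equals the contrast calibration at the current [Ca2+];
    relaxation back to baseline is exponential with ``relax_tau_s``.
    """

    fluor_f_min: float = 1.0
    fluor_f_max: float = 103.3
    fluor_kd_nM: float = 600.0
    fluor_h: float = 1.3
    contrast_c0: float = 0.75       # zero-Ca contrast plateau
    contrast_cinf: float = 0.05     # Ca-saturated plateau
    contrast_kd_nM: float = 250.0
    contrast_h: float = 1.0
    relax_tau_s: float = 0.5
    violet_s: float = 2.5
    gap_s: float = 4.0
    n_cycles: int = 5
    start_s: float = 1.0
    sampling_hz: float = 20.0
    gain: float = 1.0
    noise_cv: float = 0.0
    seed: int = 0

    def calibration(self) -> IPEAQCalibration:
        """The generating calibration pair (exact, not refitted)."""
        return IPEAQCalibration(
            HillFit(self.contrast_c0, self.contrast_cinf,
                    self.contrast_kd_nM, self.contrast_h),
            HillFit(self.fluor_f_min, self.fluor_f_max,
                    self.fluor_kd_nM, self.fluor_h),
            ca_range=(min(self.fluor_kd_nM, self.contrast_kd_nM) / 100.0,
                      max(self.fluor_kd_nM, self.contrast_kd_nM) * 100.0))


def cch_transient(t: np.ndarray, basal_nM: float = 100.0,
                  peak_nM: float = 1000.0, t_on_s: float = 0.0,
                  rise_s: float = 1.5, decay_s: float = 6.0) -> np.ndarray:
    """Smooth agonist-evoked Ca2+-release transient (alpha-like shape)."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t_on_s, 0.0, None)
    shape = (1.0 - np.exp(-dt / rise_s)) * np.exp(-dt / decay_s)
    t_pk = rise_s * np.log1p(decay_s / rise_s)
    peak_shape = (1.0 - np.exp(-t_pk / rise_s)) * np.exp(-t_pk / decay_s)
    return basal_nM + (peak_nM - basal_nM) * shape / peak_shape


def gen_photochromic(cfg: PhotochromicConfig,
                     ca_truth: Callable[[np.ndarray], np.ndarray] | float | None = 100.0,
                     duration_s: float | None = None,
                     ) -> tuple[PhotochromicTrace, dict]:
    """Forward-simulate a photochromic trace over a [Ca2+](t) trajectory.

    ``ca_truth`` may be a constant (nM) or a callable of the time grid.
    Returns the trace and a truth dict with the [Ca2+] trajectory, the
    exact generating calibration, and the cycle schedule.
    """
    rng = _rng(cfg.seed)
    contrast_fit = HillFit(cfg.contrast_c0, cfg.contrast_cinf,
                           cfg.contrast_kd_nM, cfg.contrast_h)
    fluor_fit = HillFit(cfg.fluor_f_min, cfg.fluor_f_max,
                        cfg.fluor_kd_nM, cfg.fluor_h)
    try:  # degenerate (flat-contrast) configs have no usable calibration
        cal = cfg.calibration()
    except OrientationError:
        cal = None
    cycles_end = cfg.start_s + cfg.n_cycles * (cfg.violet_s + cfg.gap_s)
    if duration_s is None:
        duration_s = cycles_end + 1.0
    t = np.arange(0.0, duration_s, 1.0 / cfg.sampling_hz)
    ca = (ca_truth(t) if callable(ca_truth)
          else np.full(t.size, float(ca_truth)))
    if np.any(ca <= 0):
        raise ConfigError("ca_truth must be positive")

    base = fluor_fit(ca)
    contrast = contrast_fit(ca)
    f = base.copy()
    violet = np.zeros(t.size, dtype=bool)
    for k in range(cfg.n_cycles):
        on = cfg.start_s + k * (cfg.violet_s + cfg.gap_s)
        off = on + cfg.violet_s
        in_epoch = (t >= on) & (t < off)
        violet |= in_epoch
        f_hv = base / (1.0 - contrast)
        f[in_epoch] = f_hv[in_epoch]
        relax = (t >= off) & (t < on + cfg.violet_s + cfg.gap_s)
        amp = f_hv - base
        f[relax] = base[relax] + amp[relax] * np.exp(-(t[relax] - off)
                                                     / cfg.relax_tau_s)
    f = _mult_noise(cfg.gain * f, cfg.noise_cv, rng)
    truth = {"ca_nM": ca, "calibration": cal, "gain": cfg.gain,
             "cycles_end_s": cycles_end, "contrast": contrast}
    return PhotochromicTrace(t, f, violet), truth


def gen_calibration_tables(cfg: PhotochromicConfig, n_points: int = 12,
                           noise_cv: float = 0.0, seed: int = 0,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In vitro calibration tables (ca_nM, contrast, fluorescence)."""
    if n_points < 5:
        raise ConfigError("need >= 5 calibration concentrations")
    rng = _rng(seed)
    cal = cfg.calibration()
    kd_lo = min(cfg.contrast_kd_nM, cfg.fluor_kd_nM)
    kd_hi = max(cfg.contrast_kd_nM, cfg.fluor_kd_nM)
    ca = np.logspace(np.log10(kd_lo) - 2, np.log10(kd_hi) + 2, n_points)
    contrast = _mult_noise(cal.contrast_curve(ca), noise_cv, rng)
    fluor = _mult_noise(cal.fluor_curve(ca), noise_cv, rng)
    return ca, contrast, fluor


# --------------------------------------------------------------------------
# Action-potential trains

@dataclass
class APTrainConfig:
    """Fluorescence transients from an AP train via kernel convolution.

    The single-AP kernel is a double exponential
    (1 - exp(-t/rise)) * exp(-t/decay), normalized to unit peak and
    scaled by ``amp_per_ap`` (absolute fluorescence units); the trace is
    baseline ``f0`` plus the summed kernels.  Presets: a fast sensor has
    half-decay 409 ms (decay tau 0.59 s), a reference fast GECI 482 ms.
    """

    rate_hz: float = 5.0
    n_aps: int = 1
    rise_s: float = 0.01
    decay_s: float = 0.59
    amp_per_ap: float = 50.0
    f0: float = 100.0
    onset_s: float = 1.0
    duration_s: float = 8.0
    sampling_hz: float = 100.0
    noise_cv: float = 0.0
    seed: int = 0


def gen_ap_train(cfg: APTrainConfig) -> tuple[FluorescenceTrace, dict]:
    if cfg.sampling_hz < 2.0 / cfg.decay_s:
        import warnings
        warnings.warn("sampling rate below twice the kernel bandwidth; "
                      "peaks will alias", UserWarning)
    rng = _rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_s, 1.0 / cfg.sampling_hz)
    f = np.full(t.size, cfg.f0)
    t_pk = cfg.rise_s * np.log1p(cfg.decay_s / cfg.rise_s)
    peak = (1.0 - np.exp(-t_pk / cfg.rise_s)) * np.exp(-t_pk / cfg.decay_s)
    spike_times = cfg.onset_s + np.arange(cfg.n_aps) / cfg.rate_hz
    for ts in spike_times:
        dt = t - ts
        m = dt >= 0
        f[m] += (cfg.amp_per_ap / peak
                 * (1.0 - np.exp(-dt[m] / cfg.rise_s))
                 * np.exp(-dt[m] / cfg.decay_s))
    f = _mult_noise(f, cfg.noise_cv, rng)
    trace = FluorescenceTrace(t, f, (0.0, cfg.onset_s),
                              stim_onsets=tuple(spike_times))
    truth = {"peak_dff": cfg.amp_per_ap / cfg.f0, "f0": cfg.f0,
             "half_decay_s": np.log(2.0) * cfg.decay_s,
             "spike_times": spike_times}
    return trace, truth


# --------------------------------------------------------------------------
# Drifting-grating tuning tables

@dataclass
class TuningConfig:
    """Trial-structured responses with a von Mises direction profile.

    The response amplitude at direction theta is
    ``r_max * exp(kappa (cos(theta - theta_pref) - 1))``; kappa = 0 is
    untuned.  Stimulus-window dF/F0 samples are the amplitude plateau
    plus additive Gaussian noise of SD ``noise_sd``.
    """

    kappa: float = 2.0
    theta_pref_deg: float = 90.0
    r_max: float = 2.0
    n_directions: int = 8
    n_trials: int = 6
    stim_s: float = 4.0
    sampling_hz: float = 10.0
    noise_sd: float = 0.1
    seed: int = 0


def gen_tuning(cfg: TuningConfig) -> tuple[pd.DataFrame, dict]:
    rng = _rng(cfg.seed)
    thetas = np.arange(cfg.n_directions) * 360.0 / cfg.n_directions
    amp = cfg.r_max * np.exp(cfg.kappa * (np.cos(
        np.deg2rad(thetas - cfg.theta_pref_deg)) - 1.0))
    t_samples = np.arange(0.0, cfg.stim_s, 1.0 / cfg.sampling_hz)
    rows = []
    for i, theta in enumerate(thetas):
        for trial in range(cfg.n_trials):
            dff = amp[i] + cfg.noise_sd * rng.standard_normal(t_samples.size)
            rows.append(pd.DataFrame({
                "roi": 0, "theta_deg": theta, "trial": trial,
                "sample_time_s": t_samples, "dff": dff}))
    table = pd.concat(rows, ignore_index=True)
    truth = {"theta_deg": thetas, "amplitude": amp,
             "theta_pref_deg": cfg.theta_pref_deg, "kappa": cfg.kappa}
    return table, truth
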