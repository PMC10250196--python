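"""Chromophore photophysics from absorbance spectra.

GFP-like chromophores of green GECIs interconvert between a neutral
(protonated) state absorbing near 403 nm and an anionic (deprotonated)
state absorbing near 509 nm.  Because the total chromophore amount is
conserved during an H+ titration, the anionic and neutral band
absorbances move in strict anticorrelation, and the slope of OD_A
against OD_N across pH equals -eps_A/eps_N.  Anchoring the absolute
scale with an alkaline-denatured spectrum (the denatured chromophore
extinction coefficient is a known constant, 44,000 M-1 cm-1) turns that
ratio into absolute extinction coefficients, state populations and a
chromophore pKa.  Quantum yields and two-photon action cross-sections
are obtained relative to standard dyes (fluorescein, TOLLES), where all
instrument constants cancel in the sample/standard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import (
    DegenerateRegressionError,
    FitQualityWarning,
    InvalidDenaturedError,
    MissingReferenceError,
    SignError,
    WindowCoverageError,
)

__all__ = [
    "AbsorbanceSpectrum",
    "PHSeries",
    "ChromophoreParams",
    "QuantumYieldData",
    "TwoPhotonPoint",
    "PkaFit",
    "SlopeFit",
    "band_amplitudes",
    "peak_od",
    "titration_slope",
    "extinction_coefficients",
    "fit_pka",
    "quantum_yield",
    "two_photon_cross_section",
    "fluorescein_cross_section",
    "NEUTRAL_WINDOW",
    "ANIONIC_WINDOW",
    "BASELINE_WINDOW",
    "EPS_DENATURED",
]

#: Band windows (nm) for the neutral (~403 nm) and anionic (~509 nm) states.
NEUTRAL_WINDOW = (380.0, 430.0)
ANIONIC_WINDOW = (470.0, 540.0)
#: Protein chromophores do not absorb here; used for baseline subtraction.
BASELINE_WINDOW = (600.0, 650.0)
#: Extinction coefficient of the alkaline-denatured GFP-like chromophore
#: (M-1 cm-1), the absolute anchor of the titration method.
EPS_DENATURED = 44_000.0

_DENATURED_PH = 11.0  # spectra at or above this pH count as denatured


@dataclass
class AbsorbanceSpectrum:
    """One absorbance spectrum with its measurement condition.

    Parameters
    ----------
    wavelength_nm : array
        Strictly increasing wavelength grid in nm.
    absorbance : array
        Optical density at each wavelength (dimensionless, 1-cm path).
    ph : float
        Buffer pH.
    ca_state : str
        ``"ca_free"`` or ``"ca_saturated"``.
    mg_present : bool
        Whether 1 mM Mg2+ was present.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    ph: float
    ca_state: str = "ca_free"
    mg_present: bool = False

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise WindowCoverageError("wavelength grid must be a 1-D array")
        if self.wavelength_nm.size != self.absorbance.size:
            raise ValueError("wavelength and absorbance must have equal length")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.ca_state not in ("ca_free", "ca_saturated"):
            raise ValueError(f"unknown ca_state {self.ca_state!r}")

    @property
    def is_denatured(self) -> bool:
        return self.ph >= _DENATURED_PH

    def covers(self, window: tuple[float, float]) -> bool:
        return (self.wavelength_nm[0] <= window[0]
                and self.wavelength_nm[-1] >= window[1])


@dataclass
class PHSeries:
    """A pH titration: several native spectra plus one denatured spectrum.

    All spectra must share the same Ca2+ state.  The denatured spectrum
    (pH >= 11, nominally 12.5) anchors the extinction-coefficient scale.
    """

    spectra: Sequence[AbsorbanceSpectrum]

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        if len({s.ca_state for s in self.spectra}) > 1:
            raise ValueError("all spectra in a PHSeries must share ca_state")
        if len(self.native) < 3:
            raise ValueError("need >= 3 non-denatured pH points")
        if len([s for s in self.spectra if s.is_denatured]) != 1:
            raise ValueError("need exactly one denatured spectrum")

    @property
    def native(self) -> list[AbsorbanceSpectrum]:
        return [s for s in self.spectra if not s.is_denatured]

    @property
    def denatured(self) -> AbsorbanceSpectrum:
        return next(s for s in self.spectra if s.is_denatured)

    def at_ph(self, ph: float, atol: float = 1e-6) -> AbsorbanceSpectrum:
        for s in self.native:
            if abs(s.ph - ph) <= atol:
                return s
        raise KeyError(f"no spectrum at pH {ph}")


@dataclass
class SlopeFit:
    """OLS slope of OD_A on OD_N across pH, with fit diagnostics."""

    slope: float
    intercept: float
    stderr: float
    residual: float  # RMS residual of the regression


@dataclass
class PkaFit:
    """Hill-sigmoid fit of the anionic fraction against pH."""

    pka: float
    h: float
    warning: str | None = None


@dataclass
class ChromophoreParams:
    """Absolute chromophore photophysics derived from a pH titration."""

    slope_s: float
    eps_n: float
    eps_a: float
    rho_a: float
    rho_n: float
    pka: float
    eps_d: float = EPS_DENATURED
    pka_fit: PkaFit | None = field(default=None, repr=False)
    slope_fit: SlopeFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if abs(self.rho_a + self.rho_n - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if abs(self.eps_a - self.eps_n * (-self.slope_s)) > 1e-6 * abs(self.eps_a):
            raise ValueError("eps_a must equal eps_n * (-S)")


def _baseline(spectrum: AbsorbanceSpectrum,
              window: tuple[float, float] = BASELINE_WINDOW) -> float:
    """Mean OD over the chromophore-free window; 0 if not covered."""
    wl = spectrum.wavelength_nm
    mask = (wl >= window[0]) & (wl <= window[1])
    if not mask.any():
        return 0.0
    return float(spectrum.absorbance[mask].mean())


def peak_od(spectrum: AbsorbanceSpectrum,
            window: tuple[float, float],
            smooth: bool = True,
            subtract_baseline: bool = True) -> float:
    """Peak absorbance within ``window`` after optional smoothing/baseline.

    A 5-point median filter suppresses single-sample glitches before
    peak-picking; the raw spectrum is never modified.  Negative results
    (noise below baseline) are clipped to 0.
    """
    if not spectrum.covers(window):
        raise WindowCoverageError(
            f"grid [{spectrum.wavelength_nm[0]}, {spectrum.wavelength_nm[-1]}] nm "
            f"does not cover window {window}")
    od = spectrum.absorbance
    if smooth and od.size >= 5:
        od = median_filter(od, size=5, mode="nearest")
    if subtract_baseline:
        od = od - _baseline(spectrum)
    wl = spectrum.wavelength_nm
    mask = (wl >= window[0]) & (wl <= window[1])
    return float(max(od[mask].max(), 0.0))


def band_amplitudes(spectrum: AbsorbanceSpectrum,
                    smooth: bool = True,
                    subtract_baseline: bool = True) -> tuple[float, float]:
    """Neutral- and anionic-band peak absorbances ``(od_n, od_a)``.

    od_n is the peak within 380-430 nm (protonated chromophore), od_a
    within 470-540 nm (deprotonated), both after baseline subtraction.
    """
    od_n = peak_od(spectrum, NEUTRAL_WINDOW, smooth, subtract_baseline)
    od_a = peak_od(spectrum, ANIONIC_WINDOW, smooth, subtract_baseline)
    return od_n, od_a


def titration_slope(series: PHSeries, **band_kw) -> SlopeFit:
    """OLS slope S = dOD_A/dOD_N across the native pH points.

    Chromophore conservation makes OD_A and OD_N strictly anticorrelated,
    so S is expected negative and equals -eps_A/eps_N.
    """
    pairs = np.array([band_amplitudes(s, **band_kw) for s in series.native])
    od_n, od_a = pairs[:, 0], pairs[:, 1]
    if np.ptp(od_n) <= 1e-12 * max(np.abs(od_n).max(), 1.0):
        raise DegenerateRegressionError(
            "OD_N constant across pH points: no titration information")
    res = linregress(od_n, od_a)
    rms = float(np.sqrt(np.mean((od_a - (res.slope * od_n + res.intercept)) ** 2)))
    return SlopeFit(float(res.slope), float(res.intercept),
                    float(res.stderr), rms)


def _sigmoid(ph: np.ndarray, pka: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (h * (pka - ph)))


def fit_pka(ph: np.ndarray, rho_a: np.ndarray, h_start: float = 1.0) -> PkaFit:
    """Fit rho_A(pH) = 1 / (1 + 10^(h (pKa - pH))) by nonlinear least squares.

    A flat anionic fraction is unidentifiable and returns NaN with a
    warning instead of raising.
    """
    ph = np.asarray(ph, dtype=float)
    rho_a = np.asarray(rho_a, dtype=float)
    if ph.size < 3:
        raise DegenerateRegressionError("need >= 3 pH points to fit a pKa")
    if np.ptp(rho_a) < 1e-9:
        msg = "anionic fraction is flat across pH; pKa unidentifiable"
        warnings.warn(msg, FitQualityWarning)
        return PkaFit(float("nan"), float("nan"), warning=msg)
    pka0 = float(ph[np.argmin(np.abs(rho_a - 0.5))])
    popt, _ = curve_fit(_sigmoid, ph, rho_a, p0=[pka0, h_start], maxfev=10_000)
    fit = PkaFit(float(popt[0]), float(popt[1]))
    order = np.argsort(ph)
    if np.any(np.diff(rho_a[order]) < -0.05 * np.ptp(rho_a)):
        fit.warning = "anionic fraction is non-monotone in pH"
        warnings.warn(fit.warning, FitQualityWarning)
    return fit


def extinction_coefficients(series: PHSeries,
                            eval_ph: float = 7.2,
                            eps_d: float = EPS_DENATURED,
                            **band_kw) -> ChromophoreParams:
    """Absolute extinction coefficients and state fractions from a pH series.

    With S the titration slope and OD_D the denatured band absorbance::

        eps_N = (OD_A/(-S) + OD_N) / (OD_D / eps_D)      (at eval_ph)
        eps_A = eps_N * (-S)
        rho_A = (OD_A/eps_A) / (OD_A/eps_A + OD_N/eps_N)

    The chromophore conservation OD_D/eps_D = OD_A/eps_A + OD_N/eps_N
    holds by construction.  The pKa is fitted from rho_A across all
    native pH points.
    """
    sfit = titration_slope(series, **band_kw)
    if sfit.slope >= 0:
        raise SignError(
            f"titration slope {sfit.slope:.4g} >= 0: OD_A/OD_N anticorrelation "
            "violated; check band assignment")
    s = sfit.slope
    den = series.denatured
    # the denatured band (~447 nm) sits between the two native windows:
    # take the peak over the full quantification range
    od_d = peak_od(den, (NEUTRAL_WINDOW[0], ANIONIC_WINDOW[1]), **band_kw)
    if od_d <= 0:
        raise InvalidDenaturedError("denatured spectrum has no absorbance band")
    n_total = od_d / eps_d

    od_n, od_a = band_amplitudes(series.at_ph(eval_ph), **band_kw)
    eps_n = (od_a / (-s) + od_n) / n_total
    eps_a = eps_n * (-s)
    n_a = od_a / eps_a
    n_n = od_n / eps_n
    rho_a = n_a / (n_a + n_n)

    phs = np.array([sp.ph for sp in series.native])
    rhos = []
    for sp in series.native:
        on, oa = band_amplitudes(sp, **band_kw)
        na, nn = oa / eps_a, on / eps_n
        rhos.append(na / (na + nn) if (na + nn) > 0 else np.nan)
    pka_fit = fit_pka(phs, np.array(rhos))

    return ChromophoreParams(
        slope_s=s, eps_n=float(eps_n), eps_a=float(eps_a),
        rho_a=float(rho_a), rho_n=float(1.0 - rho_a),
        pka=pka_fit.pka, eps_d=eps_d, pka_fit=pka_fit, slope_fit=sfit)


@dataclass
class QuantumYieldData:
    """Dilution series for relative quantum-yield determination.

    ``sample_points`` are (absorbance, total integrated fluorescence)
    pairs; the standard's TIF-vs-absorbance slope and quantum yield set
    the absolute scale (fluorescein 0.925 for the anionic chromophore at
    470 nm excitation, TOLLES 0.79 for the neutral at 405 nm).
    """

    sample_points: np.ndarray  # shape (n, 2): absorbance, TIF
    standard_slope: float
    standard_phi: float = 0.925

    def __post_init__(self) -> None:
        self.sample_points = np.atleast_2d(
            np.asarray(self.sample_points, dtype=float))
        if self.sample_points.shape[0] < 2 or self.sample_points.shape[1] != 2:
            raise ValueError("need >= 2 (absorbance, TIF) sample points")
        if np.any(self.sample_points[:, 0] < 0):
            raise ValueError("absorbances must be non-negative")


@dataclass
class QuantumYieldResult:
    phi: float
    sample_slope: float
    warning: str | None = None


def quantum_yield(data: QuantumYieldData) -> QuantumYieldResult:
    """Phi = Phi_standard * (S_sample / S_standard), slopes from OLS."""
    absorbance, tif = data.sample_points.T
    if np.ptp(absorbance) <= 1e-12 * max(np.abs(absorbance).max(), 1.0):
        raise DegenerateRegressionError(
            "sample absorbances do not span distinct values")
    if data.standard_slope == 0:
        raise ZeroDivisionError("standard slope is zero")
    slope = float(linregress(absorbance, tif).slope)
    phi = data.standard_phi * slope / data.standard_slope
    warning = None
    if phi > 1:
        warning = f"quantum yield {phi:.3f} > 1; check standard assignment"
        warnings.warn(warning, FitQualityWarning)
    return QuantumYieldResult(float(phi), slope, warning)


def fluorescein_cross_section(wavelength_nm: float) -> float:
    """Fluorescein two-photon action cross-section (GM) at ``wavelength_nm``.

    Linear interpolation of the bundled 750-990 nm reference table
    (approximate digitization of Xu & Webb, J. Opt. Soc. Am. B 13, 481
    (1996), fluorescein in water at pH ~11).
    """
    table = _fluorescein_table()
    wl, delta = table[:, 0], table[:, 1]
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise MissingReferenceError(
            f"{wavelength_nm} nm outside bundled fluorescein table "
            f"({wl[0]:.0f}-{wl[-1]:.0f} nm); supply delta_standard explicitly")
    return float(np.interp(wavelength_nm, wl, delta))


_TABLE_CACHE: np.ndarray | None = None


def _fluorescein_table() -> np.ndarray:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        ref = resources.files("gecilab").joinpath("data/fluorescein_2p.csv")
        with ref.open("rb") as fh:
            _TABLE_CACHE = np.loadtxt(fh, delimiter=",", comments="#")
    return _TABLE_CACHE


@dataclass
class TwoPhotonPoint:
    """Paired sample/standard measurement for a relative 2P cross-section.

    The time-averaged fluorescence photon fluxes must come from the same
    system at the same wavelength and laser power, so that pulse shape,
    repetition rate, pulse width, refractive index, incident power and
    collection efficiency all cancel in the sample/standard ratio.
    """

    wavelength_nm: float
    f_sample: float
    f_standard: float
    c_sample: float
    c_standard: float
    eta2_sample: float
    eta2_standard: float = 0.925  # fluorescein, assumed wavelength-independent
    delta_standard: float | None = None

    def __post_init__(self) -> None:
        for name in ("f_sample", "f_standard", "c_sample", "c_standard",
                     "eta2_sample", "eta2_standard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def two_photon_cross_section(point: TwoPhotonPoint) -> float:
    """delta_sample (GM) relative to the fluorescein standard.

    delta = (F_s * eta2_std * C_std) / (F_std * eta2_s * C_s) * delta_std
    """
    delta_std = point.delta_standard
    if delta_std is None:
        delta_std = fluorescein_cross_section(point.wavelength_nm)
    return (point.f_sample * point.eta2_standard * point.c_standard
            / (point.f_standard * point.eta2_sample * point.c_sample)
            * delta_std)
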