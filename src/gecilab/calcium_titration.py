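"""Ca2+ titration and kinetics: EGTA buffering, Hill fits, off-rates.

In vitro dose-response curves are produced by mixing 10 mM EGTA and
10 mM Ca-EGTA stocks: with equal total chelator on both sides, the free
[Ca2+] of a mixture follows the reciprocal-dilution relation
``Kd_EGTA * f / (1 - f)`` where ``f`` is the Ca-EGTA volume fraction.
Fluorescence against free [Ca2+] is fitted with a Hill equation
(specific binding with Hill slope); Ca2+ dissociation kinetics after
rapid chelation are fitted with a single exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import (
    FitQualityWarning,
    SaturatedBufferError,
    UnidentifiableFitError,
)

__all__ = [
    "CaEGTAMix",
    "TitrationCurve",
    "HillFit",
    "KineticTrace",
    "KoffFit",
    "free_calcium",
    "fit_hill",
    "dynamic_range",
    "fit_koff",
    "hill_curve",
    "KD_EGTA_NM",
]

#: EGTA-Ca2+ dissociation constant (nM) at pH 7.2, ~0.1 M ionic strength,
#: 22 C.  Overridable everywhere it is used.
KD_EGTA_NM = 150.0


@dataclass
class CaEGTAMix:
    """An EGTA / Ca-EGTA mixture defining a clamped free [Ca2+]."""

    frac_ca_egta: float
    kd_egta: float = KD_EGTA_NM

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_ca_egta <= 1.0:
            raise ValueError("frac_ca_egta must lie in [0, 1]")
        if self.kd_egta <= 0:
            raise ValueError("kd_egta must be positive")


def free_calcium(mix: CaEGTAMix) -> float:
    """Free [Ca2+] (nM) of an EGTA / Ca-EGTA mixture.

    ca_free = kd_egta * f / (1 - f).  f = 1 (pure Ca-EGTA) leaves no
    free chelator and the free concentration is unbounded.
    """
    if mix.frac_ca_egta >= 1.0:
        raise SaturatedBufferError(
            "pure Ca-EGTA stock: free [Ca2+] is unbounded")
    return mix.kd_egta * mix.frac_ca_egta / (1.0 - mix.frac_ca_egta)


def hill_curve(ca: np.ndarray, f_min: float, f_max: float,
               kd: float, h: float) -> np.ndarray:
    """F([Ca]) = f_min + (f_max - f_min) * [Ca]^h / (kd^h + [Ca]^h).

    ``f_min`` is the zero-Ca2+ plateau, ``f_max`` the saturating plateau;
    ``f_max < f_min`` describes an inverted (decreasing) response.
    """
    ca = np.asarray(ca, dtype=float)
    with np.errstate(divide="ignore"):
        frac = ca ** h / (kd ** h + ca ** h)
    return f_min + (f_max - f_min) * frac


@dataclass
class HillFit:
    """Fitted Hill parameters with standard errors.

    ``dr`` is the dynamic range (f_max - f_min)/f_min computed from the
    fitted plateaus; ``dr_raw`` (from raw data extremes) is also kept,
    flagged, because background-subtraction errors near zero inflate it.
    """

    f_min: float
    f_max: float
    kd: float
    h: float
    stderr: dict = field(default_factory=dict, repr=False)
    dr_raw: float | None = field(default=None, repr=False)

    @property
    def dr(self) -> float:
        return dynamic_range(self.f_max, self.f_min)

    def __call__(self, ca) -> np.ndarray:
        return hill_curve(ca, self.f_min, self.f_max, self.kd, self.h)


@dataclass
class TitrationCurve:
    """Fluorescence against free [Ca2+] (nM), optionally with its fit."""

    ca_free: np.ndarray
    fluorescence: np.ndarray
    fit: HillFit | None = None

    def __post_init__(self) -> None:
        self.ca_free = np.asarray(self.ca_free, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.ca_free.size != self.fluorescence.size:
            raise ValueError("ca_free and fluorescence must have equal length")
        if np.any(self.ca_free < 0) or not np.all(np.diff(self.ca_free) > 0):
            raise ValueError("ca_free must be non-negative, strictly increasing")


def fit_hill(curve: TitrationCurve | None = None,
             ca: np.ndarray | None = None,
             fluorescence: np.ndarray | None = None,
             increasing: bool = True) -> HillFit:
    """Least-squares Hill fit of fluorescence against free [Ca2+].

    Initialization: plateaus from the 5th/95th percentiles of the
    fluorescence, kd from the concentration nearest half-range, Hill
    coefficient start 2.  All parameters bounded positive.
    """
    if curve is not None:
        ca, fluorescence = curve.ca_free, curve.fluorescence
    x = np.asarray(ca, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 5:
        raise UnidentifiableFitError("need >= 5 concentrations for a Hill fit")
    span = np.ptp(y)
    # points all on one plateau are as uninformative as a constant
    if span <= 1e-6 * max(np.abs(y).max(), 1.0):
        raise UnidentifiableFitError(
            "fluorescence does not vary beyond numerical noise: "
            "kd unidentifiable (all points on one plateau?)")

    lo, hi = np.percentile(y, [5, 95])
    if not increasing:
        lo, hi = hi, lo
    half = 0.5 * (lo + hi)
    pos = x[x > 0]
    kd0 = float(pos[np.argmin(np.abs(y[x > 0] - half))]) if pos.size else 1.0

    model = Model(hill_curve)
    params = model.make_params(
        f_min=dict(value=max(lo, 1e-12), min=0),
        f_max=dict(value=max(hi, 1e-12), min=0),
        kd=dict(value=kd0, min=1e-12),
        h=dict(value=2.0, min=1e-3, max=20),
    )
    res = model.fit(y, params, ca=x)
    stderr = {name: (p.stderr if p.stderr is not None else float("nan"))
              for name, p in res.params.items()}
    fmin, fmax = res.params["f_min"].value, res.params["f_max"].value
    # plateau identifiability: both plateaus must be approached by the data
    if (x.max() < res.params["kd"].value / 3
            or (pos.size and pos.min() > res.params["kd"].value * 3)):
        raise UnidentifiableFitError(
            "concentrations do not span the transition around kd")
    dr_raw = (y.max() - y.min()) / y.min() if y.min() > 0 else None
    fit = HillFit(float(fmin), float(fmax), float(res.params["kd"].value),
                  float(res.params["h"].value), stderr, dr_raw)
    if curve is not None:
        curve.fit = fit
    return fit


def dynamic_range(f_max: float, f_min: float) -> float:
    """DR = (F_max - F_min) / F_min.

    F_min at or below zero means the minimal fluorescence was not
    resolved above background; the DR would be an artifact of background
    subtraction, so this is an error rather than a large number.
    """
    if f_min <= 0:
        raise ValueError(
            "f_min <= 0: minimal fluorescence at/below background; "
            "DR would be a background-subtraction artifact")
    return (f_max - f_min) / f_min


@dataclass
class KineticTrace:
    """Fluorescence decay after rapid Ca2+ removal by excess EGTA."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    koff: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.size != self.fluorescence.size:
            raise ValueError("time and fluorescence must have equal length")
        if not np.all(np.diff(self.time_s) > 0) or self.time_s[0] < 0:
            raise ValueError("time must be strictly increasing from >= 0")


@dataclass
class KoffFit:
    koff: float          # s^-1
    amplitude: float
    plateau: float
    stderr: dict = field(default_factory=dict, repr=False)

    @property
    def half_time_s(self) -> float:
        return np.log(2.0) / self.koff


def _single_exp(t, plateau, amplitude, koff):
    return plateau + amplitude * np.exp(-koff * t)


def fit_koff(trace: KineticTrace) -> KoffFit:
    """Single-exponential off-rate fit F(t) = plateau + A exp(-koff t)."""
    t, y = trace.time_s, trace.fluorescence
    if t.size < 10:
        raise UnidentifiableFitError("need >= 10 samples for an off-rate fit")
    span = np.ptp(y)
    if span <= 1e-12 * max(np.abs(y).max(), 1.0):
        raise UnidentifiableFitError("flat trace: koff unidentifiable")
    if y[-1] > y[0]:
        warnings.warn("trace rises rather than decays; koff sign suspect",
                      FitQualityWarning)
    plateau0 = float(y[-1])
    a0 = float(y[0] - plateau0)
    # time to fall to 1/e of the initial amplitude sets the rate scale
    target = plateau0 + a0 / np.e
    below = np.nonzero(y <= target)[0] if a0 > 0 else np.nonzero(y >= target)[0]
    t_e = t[below[0]] if below.size else t[-1] / 2
    k0 = 1.0 / max(t_e, (t[1] - t[0]))

    model = Model(_single_exp, independent_vars=["t"])
    params = model.make_params(
        plateau=dict(value=plateau0),
        amplitude=dict(value=a0),
        koff=dict(value=k0, min=1e-9),
    )
    res = model.fit(y, params, t=t)
    koff = float(res.params["koff"].value)
    # require >= 2 e-folds of decay within the record
    if koff * (t[-1] - t[0]) < 2.0:
        raise UnidentifiableFitError(
            "record covers < 2 e-folds of decay; koff unidentifiable")
    stderr = {name: (p.stderr if p.stderr is not None else float("nan"))
              for name, p in res.params.items()}
    fit = KoffFit(koff, float(res.params["amplitude"].value),
                  float(res.params["plateau"].value), stderr)
    trace.koff = koff
    return fit
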