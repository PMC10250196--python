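"""Photochromism-enabled absolute [Ca2+] quantification (iPEAQ).

Brief 405-nm illumination superimposed on continuous 488-nm excitation
transiently brightens the indicator in an inversely Ca2+-dependent way;
after the violet light switches off the fluorescence relaxes back.  One
such photochromic cycle yields the photochromism contrast
((F0 - F_end)/F0)_hv, which depends only on [Ca2+] and not on the
detector gain or indicator amount.  Two in vitro calibrations — contrast
against [Ca2+] (decreasing Hill) and fluorescence against [Ca2+]
(increasing Hill) — convert a live trace to absolute concentration:
the basal contrast gives the basal [Ca2+]; the fluorescence calibration
evaluated there, divided by the measured basal fluorescence, gives a
normalizing factor k; and [Ca2+](t) follows by inverting the
fluorescence calibration on k*F(t).  Any overall gain g cancels because
k scales as 1/g — this is what makes the readout absolute.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .calcium_titration import HillFit, fit_hill
from .errors import (
    CalibrationRangeError,
    CoverageWarning,
    NoCycleError,
    OrientationError,
)

__all__ = [
    "PhotochromicTrace",
    "CycleMetrics",
    "IPEAQCalibration",
    "QuantifiedTrace",
    "detect_cycles",
    "fit_calibrations",
    "hill_inverse",
    "quantify",
]

#: Fraction of each plateau/relaxation segment (its trailing part) used
#: for amplitude estimates; the leading part is discarded as unsettled.
PLATEAU_FRACTION = 0.25
#: Inversion domain is clipped this fraction of the plateau span away
#: from each plateau to bound error amplification.
INVERSION_MARGIN = 0.005


@dataclass
class PhotochromicTrace:
    """488-nm-excited trace with flagged 405-nm illumination epochs."""

    time_s: np.ndarray
    f: np.ndarray
    violet_on: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.violet_on = np.asarray(self.violet_on).astype(bool)
        if not (self.time_s.size == self.f.size == self.violet_on.size):
            raise ValueError("time, fluorescence, violet flags must align")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    def violet_epochs(self) -> list[tuple[int, int]]:
        """Contiguous violet blocks as [start, stop) index pairs."""
        flags = np.concatenate(([False], self.violet_on, [False])).astype(int)
        edges = np.diff(flags)
        starts = np.nonzero(edges == 1)[0]
        stops = np.nonzero(edges == -1)[0]
        return list(zip(starts, stops))


@dataclass
class CycleMetrics:
    """Per-cycle photochromism amplitudes and contrast.

    contrast = (f0_hv - f_end)/f0_hv, with f0_hv the violet-on peak
    fluorescence and f_end the relaxed 488-only fluorescence before the
    next violet onset.
    """

    f0_hv: float
    f_end: float
    complete: bool = True

    @property
    def contrast(self) -> float:
        return (self.f0_hv - self.f_end) / self.f0_hv


def _tail_mean(values: np.ndarray, fraction: float = PLATEAU_FRACTION) -> float:
    n = max(1, int(np.ceil(fraction * values.size)))
    return float(values[-n:].mean())


def _smoothed_min(values: np.ndarray, size: int = 5) -> float:
    """Minimum after light median filtering, robust to single-sample noise."""
    if values.size <= size:
        return float(values.min())
    from scipy.ndimage import median_filter
    return float(median_filter(values, size=size, mode="nearest").min())


def detect_cycles(trace: PhotochromicTrace,
                  method: str = "plateau",
                  plateau_fraction: float = PLATEAU_FRACTION,
                  relax_tol: float = 0.05) -> list[CycleMetrics]:
    """Per-cycle photochromism metrics from the violet epoch flags.

    ``method="plateau"`` (default) estimates f0_hv as the mean over the
    trailing ``plateau_fraction`` of the violet epoch and f_end as the
    mean over the trailing fraction of the following 488-only gap; both
    are unbiased under multiplicative noise.  ``method="extrema"`` uses
    the literal epoch maximum and gap minimum instead (noise-biased, but
    the textbook definition).  The last cycle's relaxation window is
    capped at the median inter-cycle gap so that whatever follows the
    cycle train (a stimulus period) cannot leak into f_end.  Cycles
    whose relaxation has not settled (gap tail still ``relax_tol``
    above the smoothed gap minimum) are flagged incomplete.
    """
    if method not in ("plateau", "extrema"):
        raise ValueError(f"unknown method {method!r}")
    epochs = trace.violet_epochs()
    if not epochs:
        raise NoCycleError("no violet illumination epoch in trace")
    gap_samples = [epochs[k + 1][0] - stop
                   for k, (_, stop) in enumerate(epochs[:-1])]
    cycles: list[CycleMetrics] = []
    for k, (start, stop) in enumerate(epochs):
        f_on = trace.f[start:stop]
        if k + 1 < len(epochs):
            gap_end = epochs[k + 1][0]
        elif gap_samples:
            gap_end = min(stop + int(np.median(gap_samples)), trace.f.size)
        else:
            gap_end = trace.f.size
        f_off = trace.f[stop:gap_end]
        if f_on.size == 0 or f_off.size == 0:
            continue
        if method == "extrema":
            f0_hv = float(f_on.max())
            f_end = float(f_off.min())
        else:
            f0_hv = _tail_mean(f_on, plateau_fraction)
            f_end = _tail_mean(f_off, plateau_fraction)
        floor = _smoothed_min(f_off)
        settled = _tail_mean(f_off, plateau_fraction) <= (1 + relax_tol) * floor
        cycles.append(CycleMetrics(f0_hv, f_end, complete=bool(settled)))
    if not cycles:
        raise NoCycleError("no complete violet-on -> off cycle in trace")
    return cycles


@dataclass
class IPEAQCalibration:
    """The two in vitro Hill calibrations that anchor iPEAQ.

    ``contrast_curve`` maps [Ca2+] (nM) to photochromism contrast
    (monotone decreasing); ``fluor_curve`` maps [Ca2+] to in vitro
    fluorescence (monotone increasing).  Both are analytically
    invertible between their plateaus.
    """

    contrast_curve: HillFit
    fluor_curve: HillFit
    ca_range: tuple[float, float] = field(default=(0.0, np.inf))

    def __post_init__(self) -> None:
        if self.contrast_curve.f_max >= self.contrast_curve.f_min:
            raise OrientationError("contrast calibration must be decreasing")
        if self.fluor_curve.f_max <= self.fluor_curve.f_min:
            raise OrientationError("fluorescence calibration must be increasing")

    def to_json(self) -> str:
        def pack(h: HillFit) -> dict:
            return {"f_min": h.f_min, "f_max": h.f_max, "kd": h.kd, "h": h.h}
        return json.dumps({"contrast_curve": pack(self.contrast_curve),
                           "fluor_curve": pack(self.fluor_curve),
                           "ca_range": list(self.ca_range)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "IPEAQCalibration":
        obj = json.loads(text)
        return cls(HillFit(**obj["contrast_curve"]),
                   HillFit(**obj["fluor_curve"]),
                   tuple(obj.get("ca_range", (0.0, np.inf))))


def fit_calibrations(ca_contrast: np.ndarray, contrasts: np.ndarray,
                     ca_fluor: np.ndarray, fluors: np.ndarray) -> IPEAQCalibration:
    """Fit the contrast (decreasing) and fluorescence (increasing) curves."""
    c_fit = fit_hill(ca=ca_contrast, fluorescence=contrasts, increasing=False)
    f_fit = fit_hill(ca=ca_fluor, fluorescence=fluors, increasing=True)
    if c_fit.f_max >= c_fit.f_min:
        raise OrientationError(
            "contrast increases with [Ca2+]; expected inverse dependence")
    if f_fit.f_max <= f_fit.f_min:
        raise OrientationError(
            "fluorescence decreases with [Ca2+]; expected direct dependence")
    lo = min(np.min(ca_contrast[ca_contrast > 0], initial=np.inf),
             np.min(ca_fluor[ca_fluor > 0], initial=np.inf))
    hi = max(np.max(ca_contrast), np.max(ca_fluor))
    return IPEAQCalibration(c_fit, f_fit, (float(lo), float(hi)))


def hill_inverse(fit: HillFit, y, clip: bool = False,
                 margin: float = INVERSION_MARGIN):
    """Invert a Hill curve analytically: y -> [Ca2+] (nM).

    With u = (y - f_min)/(f_max - f_min), the inverse is
    kd * (u/(1-u))^(1/h).  Values outside the open plateau range are an
    error unless ``clip=True``, in which case u is clipped to
    [margin, 1-margin] (bounding the error amplification near the
    plateaus) and the clipped positions are reported via the second
    return value.
    """
    y = np.asarray(y, dtype=float)
    span = fit.f_max - fit.f_min
    u = (y - fit.f_min) / span
    out_of_range = (u <= 0) | (u >= 1)
    if not clip:
        if np.any(out_of_range):
            raise CalibrationRangeError(
                "value outside the open range of the calibration curve")
        uc = u
    else:
        uc = np.clip(u, margin, 1.0 - margin)
    ca = fit.kd * (uc / (1.0 - uc)) ** (1.0 / fit.h)
    if clip:
        return ca, out_of_range
    return ca if ca.ndim else float(ca)


@dataclass
class QuantifiedTrace:
    """Absolute [Ca2+](t) recovered from a live photochromic trace."""

    time_s: np.ndarray
    ca_nM: np.ndarray               # NaN where violet/relaxation masked
    basal_ca_nM: float
    basal_contrast: float
    norm_factor: float              # k: in vitro per measured fluorescence
    out_of_range: np.ndarray        # clipped-sample flags
    valid: np.ndarray               # samples usable for Ca2+ readout


def quantify(live: PhotochromicTrace,
             cal: IPEAQCalibration,
             n_basal_cycles: int | None = None,
             settle_s: float | None = None,
             method: str = "plateau") -> QuantifiedTrace:
    """Convert a live photochromic trace to absolute [Ca2+] (nM).

    Steps: (1) basal contrast = mean over the initial complete cycles
    (all of them, or the first ``n_basal_cycles``); (2) basal [Ca2+]
    from the inverse contrast calibration; (3) normalizing factor
    k = fluor_curve(basal [Ca2+]) / measured basal fluorescence, the
    basal fluorescence being the mean of the settled 488-only segments
    between cycles; (4) [Ca2+](t) = fluor_curve^-1(k F(t)), clipped to
    the calibrated range with out-of-range flags.  Samples during violet
    epochs or within ``settle_s`` after a violet offset are masked NaN.
    """
    cycles = detect_cycles(live, method=method)
    if n_basal_cycles is not None:
        cycles = cycles[:n_basal_cycles]
    used = [c for c in cycles if c.complete] or cycles
    basal_contrast = float(np.mean([c.contrast for c in used]))

    c_curve = cal.contrast_curve
    c_lo, c_hi = sorted((c_curve.f_min, c_curve.f_max))
    if not (c_lo < basal_contrast < c_hi):
        raise CalibrationRangeError(
            f"basal contrast {basal_contrast:.4g} outside the open range "
            f"({c_lo:.4g}, {c_hi:.4g}) of the contrast calibration")
    basal_ca = float(hill_inverse(c_curve, basal_contrast))
    if not (cal.ca_range[0] <= basal_ca <= cal.ca_range[1]):
        warnings.warn(
            "basal [Ca2+] outside the concentrations used for calibration",
            CoverageWarning)

    epochs = live.violet_epochs()
    t = live.time_s
    gaps = [t[epochs[k + 1][0]] - t[min(stop, t.size - 1)]
            for k, (_, stop) in enumerate(epochs[:-1])]
    if settle_s is None:
        ref_gap = float(np.median(gaps)) if gaps else float(t[-1] - t[epochs[-1][1] - 1])
        settle_s = (1.0 - PLATEAU_FRACTION) * ref_gap

    # settled 488-only samples between consecutive cycles -> basal F
    basal_mask = np.zeros(t.size, dtype=bool)
    for k, (_, stop) in enumerate(epochs):
        if k + 1 < len(epochs):
            hi_idx = epochs[k + 1][0]
        elif len(epochs) == 1:
            hi_idx = t.size
        else:
            break  # after the last basal cycle the stimulus period may start
        t_off = t[stop] if stop < t.size else t[-1]
        basal_mask[stop:hi_idx] = t[stop:hi_idx] >= t_off + settle_s
    if not basal_mask.any():
        raise NoCycleError("no settled 488-only samples between basal cycles")
    basal_f = float(live.f[basal_mask].mean())
    if basal_f <= 0:
        raise ValueError("non-positive basal fluorescence")

    k_factor = float(cal.fluor_curve(basal_ca)) / basal_f
    if k_factor <= 0:
        raise ValueError("non-positive normalizing factor")

    ca_t, oor = hill_inverse(cal.fluor_curve, k_factor * live.f, clip=True)
    valid = ~live.violet_on
    for _, stop in epochs:
        if stop < t.size:
            valid &= ~((t >= t[stop]) & (t < t[stop] + settle_s))
    ca_out = np.where(valid, ca_t, np.nan)
    return QuantifiedTrace(t, ca_out, basal_ca, basal_contrast,
                           k_factor, oor & valid, valid)
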