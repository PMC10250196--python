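"""ROI fluorescence-trace metrics: dF/F0, peak SNR, decay, ratiometrics.

The signal-to-baseline ratio dF/F0 = (F - F0)/F0 with F0 the mean
fluorescence in a pre-stimulus baseline window is the primary response
metric for intensiometric indicators.  Peak SNR divides the peak dF/F0
by the baseline dF/F0 standard deviation; response decay is summarized
by the half-decay time of an exponential fit from the peak.  Dual-
excitation ratiometric traces (488/405 or 470/410 nm) cancel motion and
gain artifacts through a Ca2+-independent reference channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

from .errors import (
    BaselineError,
    ChannelError,
    FitQualityWarning,
    InsufficientReplicationError,
)

__all__ = [
    "FluorescenceTrace",
    "ResponseMetrics",
    "RatiometricTrace",
    "delta_f_over_f",
    "peak_snr",
    "half_decay_time",
    "response_metrics",
    "ratiometric",
    "responsive_cell_test",
]

#: Default window (s) after stimulus onset searched for the peak response.
DEFAULT_RESPONSE_WINDOW_S = 6.0


@dataclass
class FluorescenceTrace:
    """One ROI time series with its baseline window and stimulus onsets.

    ``baseline_window`` is a half-open interval [t0, t1) in seconds; it
    must end at or before the first stimulus onset.  The in vivo
    convention is a 1-s baseline before onset; slice-style recordings
    use 0.5 s.
    """

    time_s: np.ndarray
    f: np.ndarray
    baseline_window: tuple[float, float]
    stim_onsets: tuple = ()

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time_s.size != self.f.size:
            raise ValueError("time and fluorescence must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("fluorescence must be finite")
        t0, t1 = self.baseline_window
        if t1 <= t0:
            raise BaselineError("empty baseline window")
        self.stim_onsets = tuple(float(t) for t in self.stim_onsets)
        if self.stim_onsets and min(self.stim_onsets) < t1:
            raise BaselineError("baseline window must precede the first onset")

    def baseline_mask(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return (self.time_s >= t0) & (self.time_s < t1)


def delta_f_over_f(trace: FluorescenceTrace, background: float = 0.0) -> np.ndarray:
    """dF/F0 = (F - F0)/F0 with F0 the mean baseline fluorescence.

    ``background`` (camera offset / autofluorescence) is subtracted from
    the whole trace before F0 is computed.
    """
    mask = trace.baseline_mask()
    if mask.sum() < 3:
        raise BaselineError("baseline window contains < 3 samples")
    f = trace.f - background
    f0 = f[mask].mean()
    if f0 <= 0:
        raise BaselineError(f"non-positive baseline F0 = {f0:.4g}")
    return (f - f0) / f0


def _response_slice(trace: FluorescenceTrace,
                    response_window_s: float) -> np.ndarray:
    if not trace.stim_onsets:
        raise ValueError("trace has no stimulus onsets")
    onset = trace.stim_onsets[0]
    return (trace.time_s >= onset) & (trace.time_s <= onset + response_window_s)


def peak_snr(trace: FluorescenceTrace,
             response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
             background: float = 0.0) -> float:
    """Peak dF/F0 after the first onset over the baseline dF/F0 SD.

    A zero baseline variance (noiseless input) yields +inf with a
    warning rather than an exception.
    """
    dff = delta_f_over_f(trace, background)
    sd = float(dff[trace.baseline_mask()].std(ddof=1))
    peak = float(dff[_response_slice(trace, response_window_s)].max())
    if sd == 0:
        warnings.warn("zero baseline variance: peak SNR undefined (inf)",
                      FitQualityWarning)
        return float("inf")
    return peak / sd


def _decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def half_decay_time(trace: FluorescenceTrace,
                    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
                    background: float = 0.0) -> float:
    """Half-decay time (s) of the response after its peak.

    dF/F0 from the peak to the end of the trace is fitted with
    A exp(-(t - t_peak)/tau) + c (A, tau > 0); the half-decay time is
    ln(2) tau, invariant to A and c.
    """
    dff = delta_f_over_f(trace, background)
    sel = _response_slice(trace, response_window_s)
    idx = np.nonzero(sel)[0]
    i_peak = idx[np.argmax(dff[sel])]
    t = trace.time_s[i_peak:] - trace.time_s[i_peak]
    y = dff[i_peak:]
    if t.size < 6:
        raise ValueError("need >= 5 samples after the peak to fit a decay")
    if y[-1] > y[0]:
        warnings.warn("tail rises after the peak; decay fit suspect",
                      FitQualityWarning)
    a0 = max(y[0] - y[-1], 1e-12)
    below = np.nonzero(y <= y[-1] + a0 / np.e)[0]
    tau0 = t[below[0]] if below.size and below[0] > 0 else max(t[-1] / 2, 1e-3)
    popt, _ = curve_fit(
        _decay, t, y, p0=[a0, tau0, y[-1]],
        bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10_000)
    return float(np.log(2.0) * popt[1])


@dataclass
class ResponseMetrics:
    """Summary metrics of one stimulus-evoked response."""

    peak_sbr: float
    sd_baseline: float
    peak_snr: float
    half_decay_s: float | None = None


def response_metrics(trace: FluorescenceTrace,
                     response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
                     background: float = 0.0,
                     fit_decay: bool = True) -> ResponseMetrics:
    """Peak dF/F0, baseline SD, peak SNR and (optionally) half-decay time."""
    dff = delta_f_over_f(trace, background)
    sd = float(dff[trace.baseline_mask()].std(ddof=1))
    peak = float(dff[_response_slice(trace, response_window_s)].max())
    snr = peak / sd if sd > 0 else float("inf")
    half = None
    if fit_decay:
        try:
            half = half_decay_time(trace, response_window_s, background)
        except (ValueError, RuntimeError):
            half = None
    return ResponseMetrics(peak, sd, snr, half)


@dataclass
class RatiometricTrace:
    """Samplewise signal/reference ratio on the signal's time grid."""

    time_s: np.ndarray
    ratio: np.ndarray
    f_signal: np.ndarray = field(repr=False, default=None)
    f_reference: np.ndarray = field(repr=False, default=None)

    def as_trace(self, baseline_window: tuple[float, float],
                 stim_onsets: tuple = ()) -> FluorescenceTrace:
        """View the ratio as a trace so dR/R0 metrics reuse delta_f_over_f."""
        return FluorescenceTrace(self.time_s, self.ratio,
                                 baseline_window, stim_onsets)


def ratiometric(signal: FluorescenceTrace,
                reference: FluorescenceTrace) -> RatiometricTrace:
    """Signal/reference ratio after aligning the channels in time.

    The reference channel is linearly interpolated onto the signal grid
    over the overlapping support only (no extrapolation).  Common
    multiplicative artifacts (motion, excitation-power drift) cancel in
    the ratio.
    """
    lo = max(signal.time_s[0], reference.time_s[0])
    hi = min(signal.time_s[-1], reference.time_s[-1])
    if hi <= lo:
        raise ValueError("channels have no overlapping time support")
    keep = (signal.time_s >= lo) & (signal.time_s <= hi)
    t = signal.time_s[keep]
    ref = np.interp(t, reference.time_s, reference.f)
    if np.any(ref <= 0):
        raise ChannelError("reference channel crosses <= 0")
    sig = signal.f[keep]
    return RatiometricTrace(t, sig / ref, sig, ref)


def responsive_cell_test(stim_means: np.ndarray,
                         baseline_means: np.ndarray,
                         alpha: float = 0.01,
                         welch: bool = False) -> tuple[float, bool]:
    """Two-sample t-test of per-trial stimulus vs baseline dF/F0 means.

    Classical equal-variance Student's t-test, two-tailed, by default;
    ``welch=True`` drops the equal-variance assumption.  A cell is
    responsive when p < ``alpha`` (default 0.01) at its optimal stimulus.
    """
    stim = np.asarray(stim_means, dtype=float)
    base = np.asarray(baseline_means, dtype=float)
    if stim.size < 2 or base.size < 2:
        raise InsufficientReplicationError(
            "need >= 2 trials per condition for a t-test")
    res = ttest_ind(stim, base, equal_var=not welch)
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant samples
        p = 1.0
    return p, p < alpha
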