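"""Orientation/direction selectivity from drifting-grating responses.

Visual responses are summarized per stimulus direction by the mean
dF/F0 amplitude: within each trial, the mean of the top quartile of
samples during the stimulus window, then averaged over trials.  The
orientation selectivity index (OSI) is the normalized magnitude of the
resultant of the responses on the doubled-angle circle; the direction
selectivity index (DSI) contrasts the preferred direction with its
opposite, (R_pref - R_opp)/(R_pref + R_opp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitQualityWarning

__all__ = ["TuningCurve", "mean_amplitude", "osi", "dsi", "curve_from_trials"]


@dataclass
class TuningCurve:
    """Mean dF/F0 amplitude per drifting-grating direction."""

    theta_deg: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.theta_deg.size != self.r.size or self.theta_deg.size < 4:
            raise ValueError("need >= 4 matched (theta, r) pairs")
        if np.unique(self.theta_deg).size != self.theta_deg.size:
            raise ValueError("directions must be distinct")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("responses must be finite")
        order = np.argsort(self.theta_deg)
        self.theta_deg = self.theta_deg[order]
        self.r = self.r[order]
        spacings = np.diff(np.concatenate(
            (self.theta_deg, [self.theta_deg[0] + 360.0])))
        if not np.allclose(spacings, spacings[0]):
            raise ValueError("directions must be equally spaced over 360 deg")


def mean_amplitude(stim_samples: Sequence[np.ndarray] | np.ndarray) -> float:
    """Trial-averaged mean of the top 25% of stimulus-window samples.

    ``stim_samples`` holds the dF/F0 samples of the stimulus window, one
    array (or row) per trial.  Within each trial the largest
    ceil(n/4) samples are averaged; trials are then averaged.  This
    top-quartile estimator is positively biased on pure noise but robust
    to response-onset jitter.
    """
    trials = [np.asarray(s, dtype=float).ravel() for s in np.atleast_2d(stim_samples)] \
        if isinstance(stim_samples, np.ndarray) else \
        [np.asarray(s, dtype=float).ravel() for s in stim_samples]
    if not trials:
        raise ValueError("need >= 1 trial")
    per_trial = []
    for s in trials:
        if s.size < 4:
            raise ValueError("need >= 4 samples per stimulus window")
        k = int(np.ceil(0.25 * s.size))
        per_trial.append(np.sort(s)[-k:].mean())
    return float(np.mean(per_trial))


def osi(curve: TuningCurve) -> float:
    """Orientation selectivity index on the doubled-angle circle.

    OSI = |sum_i r_i exp(2i theta_i)| / sum_i r_i, in [0, 1].  Negative
    mean amplitudes (noise at non-preferred directions) are clipped to 0
    since the resultant formula assumes non-negative weights.  An
    all-zero curve is undefined and returns NaN with a warning.
    """
    r = np.clip(curve.r, 0.0, None)
    total = r.sum()
    if total == 0:
        warnings.warn("all-zero tuning curve: OSI undefined", FitQualityWarning)
        return float("nan")
    theta = np.deg2rad(curve.theta_deg)
    resultant = np.hypot((r * np.sin(2 * theta)).sum(),
                         (r * np.cos(2 * theta)).sum())
    return float(resultant / total)


def dsi(curve: TuningCurve) -> float:
    """Direction selectivity index (R_pref - R_opp)/(R_pref + R_opp).

    The preferred direction is the argmax of r (ties: lowest angle);
    the opposite direction must exist on the grid.  R_pref + R_opp = 0
    is undefined and returns NaN with a warning.
    """
    r = np.clip(curve.r, 0.0, None)
    i_pref = int(np.argmax(r))  # sorted thetas -> ties resolve to lowest angle
    theta_opp = (curve.theta_deg[i_pref] + 180.0) % 360.0
    match = np.isclose(curve.theta_deg % 360.0, theta_opp)
    if not match.any():
        raise ValueError(f"opposite angle {theta_opp} deg not in direction grid")
    r_pref, r_opp = r[i_pref], float(r[match][0])
    if r_pref + r_opp == 0:
        warnings.warn("R_pref + R_opp = 0: DSI undefined", FitQualityWarning)
        return float("nan")
    return float((r_pref - r_opp) / (r_pref + r_opp))


def curve_from_trials(trials: pd.DataFrame,
                      theta_col: str = "theta_deg",
                      trial_col: str = "trial",
                      value_col: str = "dff") -> TuningCurve:
    """Build a TuningCurve from a long-format trial table.

    Each (theta, trial) group holds the stimulus-window dF/F0 samples;
    the per-direction response is their top-quartile mean averaged over
    trials (see :func:`mean_amplitude`).
    """
    thetas, amps = [], []
    for theta, sub in trials.groupby(theta_col, sort=True):
        samples = [g[value_col].to_numpy()
                   for _, g in sub.groupby(trial_col, sort=True)]
        thetas.append(float(theta))
        amps.append(mean_amplitude(samples))
    return TuningCurve(np.array(thetas), np.array(amps))
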