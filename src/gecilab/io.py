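"""Reading and writing the plain-text formats used by the toolkit.

All tabular inputs are delimited text (whitespace or comma) with
``#`` comments; spectra are two columns (wavelength nm, value), traces
have time in the first column, and condition metadata travels in YAML
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ipeaq import PhotochromicTrace
from .photophysics import AbsorbanceSpectrum, PHSeries
from .trace_analysis import FluorescenceTrace

__all__ = [
    "read_table",
    "read_spectrum",
    "read_ph_series",
    "read_trace_table",
    "read_onsets",
    "read_photochromic",
    "read_trial_table",
    "write_report",
]


def read_table(path: str | Path, **kw) -> pd.DataFrame:
    """Delimited text (comma or whitespace), '#' comments, header optional."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", sep=None, engine="python", **kw)
    # header optional: treat a fully numeric header row as data
    try:
        header = [float(c) for c in df.columns]
    except (TypeError, ValueError):
        return df
    first = pd.DataFrame([header], columns=df.columns)
    df = pd.concat([first, df], ignore_index=True)
    df.columns = range(df.shape[1])
    return df


def read_spectrum(path: str | Path, ph: float,
                  ca_state: str = "ca_free",
                  mg_present: bool = False) -> AbsorbanceSpectrum:
    """Two-column (wavelength_nm, absorbance) spectrum file."""
    arr = read_table(path).to_numpy(dtype=float)
    return AbsorbanceSpectrum(arr[:, 0], arr[:, 1], ph, ca_state, mg_present)


def read_ph_series(yaml_path: str | Path) -> PHSeries:
    """A pH series described by a YAML sidecar.

    Format::

        ca_state: ca_saturated
        mg_present: false
        spectra:
          - {path: ph7.csv, ph: 7.0}
          - {path: ph12p5.csv, ph: 12.5}

    Relative paths resolve against the YAML file's directory.
    """
    yaml_path = Path(yaml_path)
    with open(yaml_path) as fh:
        spec = yaml.safe_load(fh)
    ca_state = spec.get("ca_state", "ca_free")
    mg = bool(spec.get("mg_present", False))
    spectra = [
        read_spectrum(yaml_path.parent / entry["path"], float(entry["ph"]),
                      ca_state, mg)
        for entry in spec["spectra"]
    ]
    return PHSeries(spectra)


def read_trace_table(path: str | Path,
                     baseline_window: tuple[float, float],
                     stim_onsets: tuple = ()) -> list[FluorescenceTrace]:
    """Trace table: first column time_s, remaining columns one ROI each."""
    arr = read_table(path).to_numpy(dtype=float)
    t = arr[:, 0]
    return [FluorescenceTrace(t, arr[:, j], baseline_window, stim_onsets)
            for j in range(1, arr.shape[1])]


def read_onsets(path: str | Path) -> tuple:
    """Event file: one stimulus-onset time (s) per line."""
    return tuple(np.atleast_1d(np.loadtxt(path, comments="#", ndmin=1)))


def read_photochromic(path: str | Path) -> PhotochromicTrace:
    """Photochromic trace: columns time_s, fluorescence, violet_on (0/1)."""
    arr = read_table(path).to_numpy(dtype=float)
    return PhotochromicTrace(arr[:, 0], arr[:, 1], arr[:, 2] > 0.5)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Tuning trial table: roi, theta_deg, trial, sample_time_s, dff."""
    df = read_table(path)
    required = {"roi", "theta_deg", "trial", "dff"}
    missing = required - set(map(str, df.columns))
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    return df


def write_report(results: dict, path: str | Path | None = None) -> str:
    """Flat key-value report as JSON; also returns a human-readable text."""
    clean = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in results.items()}
    text = json.dumps(clean, indent=1, default=str)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
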