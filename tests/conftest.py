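import numpy as np
import pytest

from gecilab import photophysics as pp
from gecilab import synthetic_data as sd


def make_band_spectrum(od_n: float, od_a: float, ph: float,
                       od_d: float = 0.0, fwhm: float = 25.0,
                       ca_state: str = "ca_saturated") -> pp.AbsorbanceSpectrum:
    """Spectrum with prescribed band peak amplitudes (no noise)."""
    wl = np.arange(360.0, 660.0, 1.0)
    od = (od_n * sd._gauss(wl, 403.0, fwhm)
          + od_a * sd._gauss(wl, 509.0, fwhm)
          + od_d * sd._gauss(wl, 447.0, fwhm))
    return pp.AbsorbanceSpectrum(wl, od, ph, ca_state)


def make_series(pairs, od_d: float = 0.5) -> pp.PHSeries:
    """PHSeries with given (od_n, od_a) pairs at pH 7, 7.2, 8, 9, ..."""
    phs = [7.0, 7.2, 8.0, 9.0, 6.5, 6.0][: len(pairs)]
    spectra = [make_band_spectrum(on, oa, ph)
               for (on, oa), ph in zip(pairs, phs)]
    spectra.append(make_band_spectrum(0.0, 0.0, 12.5, od_d=od_d))
    return pp.PHSeries(spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
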