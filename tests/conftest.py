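import numpy as np
import pytest

from eislope.montage import load_rsn_map, network_channels


@pytest.fixture(scope="session")
def rsn_map():
    return load_rsn_map()


@pytest.fixture(scope="session")
def da_labels():
    return tuple(network_channels()["DA"])


def periodogram_band_slope(x, fs, f_lo, f_hi):
    """Independent oracle: OLS log-log slope of the raw periodogram of a
    signal (or of a seed-averaged stack) inside [f_lo, f_hi]."""
    x = np.atleast_2d(np.asarray(x, float))
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    power = spec.mean(axis=0)
    f = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    m = (f >= f_lo) & (f <= f_hi)
    slope = np.polyfit(np.log10(f[m]), np.log10(power[m]), 1)[0]
    return slope
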