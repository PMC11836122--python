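"""Irregular-resampling auto-spectral analysis (IRASA).

IRASA separates a power spectrum into a broadband fractal (aperiodic, 1/f^b)
component and a residual oscillatory component. For every rescaling factor
``h > 1`` the signal is resampled by ``h`` and by ``1/h``; a narrowband
oscillation at f0 moves to f0/h and f0*h in the two auto-spectra, while a
scale-free power law is invariant under the geometric mean
``sqrt(S_up(f) * S_down(f))``. The fractal spectrum is the median of these
geometric means across the h set, and the oscillatory spectrum is the mixed
(raw) spectrum minus the fractal one.

Three numerically interchangeable resampling engines are provided:

``poly``
    Rational-approximation polyphase resampling with anti-alias filtering
    (the default, and the closest to common reference implementations).
``fourier``
    Ideal (sinc) resampling via FFT zero-padding/truncation.
``spectral``
    Closed form of ideal Fourier resampling: because a Hann taper scales
    with the signal it is applied to, the tapered periodogram of an ideally
    time-stretched signal equals the original tapered periodogram with a
    rescaled frequency axis. One fine-grid periodogram per epoch therefore
    yields every (h, 1/h) pair by frequency-axis lookup, which is an order
    of magnitude faster and is used for large Monte-Carlo runs. Computed in
    float32 (slope estimates are insensitive at this precision).

Cross-engine agreement on the resulting band slopes is enforced by the test
suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

from .core import InvalidArgumentError

_ENGINES = ("poly", "fourier", "spectral")

#: Oversampling of the analysis grid used by the ``spectral`` engine when it
#: interpolates the periodogram at rescaled frequencies.
_FINE_FACTOR = 4


@dataclass(frozen=True)
class IrasaConfig:
    """IRASA parameters.

    h_set: rescaling factors, all > 1 (default 1.1 .. 2.6 in 0.1 steps).
    f_min, f_max: analysis band edges in Hz (default 1 and 45).
    freq_resolution: spacing of the analysis frequency grid in Hz; epochs
        whose natural resolution is coarser are zero-padded (default 0.0625,
        i.e. an 8 s epoch is padded two-fold).
    taper: window name understood by scipy.signal.get_window.
    """

    h_set: tuple[float, ...] = tuple(round(1.1 + 0.1 * i, 1) for i in range(16))
    f_min: float = 1.0
    f_max: float = 45.0
    freq_resolution: float = 0.0625
    taper: str = "hann"

    def __post_init__(self) -> None:
        if any(h <= 1 for h in self.h_set):
            raise InvalidArgumentError("every rescaling factor h must exceed 1")
        if not self.h_set:
            raise InvalidArgumentError("h_set must be non-empty")
        if not 0 < self.f_min < self.f_max:
            raise InvalidArgumentError("need 0 < f_min < f_max")
        if self.freq_resolution <= 0:
            raise InvalidArgumentError("freq_resolution must be positive")

    @property
    def h_max(self) -> float:
        return max(self.h_set)

    def validate_fs(self, fs: float) -> None:
        """The compressed (1/h) spectrum must retain content up to
        f_max * h_max, so fs must be at least twice that."""
        need = 2.0 * self.f_max * self.h_max
        if fs < need:
            raise InvalidArgumentError(
                f"fs={fs} Hz too low for f_max={self.f_max}, "
                f"max h={self.h_max}: need fs >= {need} Hz"
            )
        nfft = fs / self.freq_resolution
        if abs(nfft - round(nfft)) > 1e-9:
            raise InvalidArgumentError(
                "fs / freq_resolution must be integral "
                f"(got {fs}/{self.freq_resolution})"
            )

    def band_freqs(self) -> np.ndarray:
        n0 = int(round(self.f_min / self.freq_resolution))
        n1 = int(round(self.f_max / self.freq_resolution))
        return np.arange(n0, n1 + 1) * self.freq_resolution


@dataclass
class SpectrumSet:
    """Mixed, fractal, and oscillatory spectra for one analysis window.

    Power is one-sided spectral density (uV^2/Hz) on a common grid spanning
    [f_min, f_max]; ``oscillatory = mixed - fractal`` holds exactly by
    construction.
    """

    freqs: np.ndarray
    mixed: np.ndarray
    fractal: np.ndarray
    oscillatory: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.oscillatory = self.mixed - self.fractal


def _check_epoch(epoch: np.ndarray, fs: float, cfg: IrasaConfig) -> np.ndarray:
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    if epoch.shape[1] < 2:
        raise InvalidArgumentError("epoch too short")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    if epoch.shape[1] / fs < 1.0 / cfg.f_min:
        raise InvalidArgumentError(
            f"epoch of {epoch.shape[1] / fs:.3f} s is shorter than one cycle "
            f"of f_min={cfg.f_min} Hz"
        )
    return epoch


def _nfft_base(fs: float, cfg: IrasaConfig) -> int:
    return int(round(fs / cfg.freq_resolution))


def _periodogram_on_grid(
    x: np.ndarray, fs: float, cfg: IrasaConfig, nfft0: int
) -> np.ndarray:
    """Hann-tapered periodogram subsampled to the freq_resolution grid.

    Signals longer than nfft0 use the smallest multiple of nfft0 that fits,
    so grid bins stay exact.
    """
    n = x.shape[-1]
    k = max(1, int(np.ceil(n / nfft0)))
    _, p = _sig.periodogram(
        x, fs=fs, window=cfg.taper, nfft=k * nfft0, detrend="constant", axis=-1
    )
    return p[..., ::k]


def compute_mixed_psd(
    epoch: np.ndarray, fs: float, cfg: IrasaConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of an epoch on the configured frequency grid.

    Returns the full grid from 0 to fs/2 at cfg.freq_resolution spacing
    (zero-padded when the epoch is shorter than fs/freq_resolution samples).
    """
    cfg = cfg or IrasaConfig()
    epoch = _check_epoch(epoch, fs, cfg)
    nfft0 = _nfft_base(fs, cfg)
    p = _periodogram_on_grid(epoch, fs, cfg, nfft0)
    freqs = np.arange(p.shape[-1]) * cfg.freq_resolution
    return freqs, p


def _band_slice(cfg: IrasaConfig) -> slice:
    lo = int(round(cfg.f_min / cfg.freq_resolution))
    hi = int(round(cfg.f_max / cfg.freq_resolution))
    return slice(lo, hi + 1)


def _irasa_poly(x, fs, cfg, nfft0, fourier=False):
    band = _band_slice(cfg)
    geo = np.empty((len(cfg.h_set), x.shape[0], band.stop - band.start))
    n = x.shape[-1]
    for i, h in enumerate(cfg.h_set):
        if fourier:
            up = _sig.resample(x, int(round(n * h)), axis=-1)
            dn = _sig.resample(x, int(round(n / h)), axis=-1)
        else:
            fr = Fraction(h).limit_denominator(1000)
            up = _sig.resample_poly(x, fr.numerator, fr.denominator, axis=-1)
            dn = _sig.resample_poly(x, fr.denominator, fr.numerator, axis=-1)
        s_up = _periodogram_on_grid(up, fs, cfg, nfft0)[..., band]
        s_dn = _periodogram_on_grid(dn, fs, cfg, nfft0)[..., band]
        geo[i] = np.sqrt(s_up * s_dn)
    return geo


def _irasa_spectral(x, fs, cfg, nfft0):
    """Fine-grid periodogram + frequency-axis rescaling (see module docs)."""
    nfft = _FINE_FACTOR * nfft0
    n = x.shape[-1]
    k = max(1, int(np.ceil(n / nfft)))
    win = _sig.get_window(cfg.taper, n)
    scale = 2.0 / (fs * (win * win).sum())
    xw = (x * win).astype(np.float32)
    spec = np.fft.rfft(xw, n=k * nfft, axis=-1)
    s_fine = (spec.real**2 + spec.imag**2) * np.float32(scale)
    df = fs / (k * nfft)
    bf = cfg.band_freqs()
    geo = np.empty((len(cfg.h_set), x.shape[0], bf.size), dtype=np.float32)
    for i, h in enumerate(cfg.h_set):
        pair = []
        for fq in (bf * h, bf / h):
            idx = fq / df
            i0 = np.floor(idx).astype(np.intp)
            w = (idx - i0).astype(np.float32)
            pair.append(s_fine[:, i0] * (1.0 - w) + s_fine[:, i0 + 1] * w)
        geo[i] = np.sqrt(pair[0] * pair[1])
    mixed = s_fine[:, :: _FINE_FACTOR * k][:, _band_slice(cfg)].astype(np.float64)
    return geo, mixed


def irasa_batch(
    x: np.ndarray, fs: float, cfg: IrasaConfig, engine: str = "poly"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRASA over a stack of equal-length epochs.

    x is (rows, samples) where rows may mix channels and window positions.
    Returns (band frequencies, mixed PSD, fractal PSD), the spectra as
    (rows, n_freqs) restricted to [f_min, f_max].
    """
    if engine not in _ENGINES:
        raise InvalidArgumentError(f"unknown engine {engine!r}; use one of {_ENGINES}")
    cfg.validate_fs(fs)
    x = _check_epoch(x, fs, cfg)
    nfft0 = _nfft_base(fs, cfg)
    if engine == "spectral":
        geo, mixed = _irasa_spectral(x, fs, cfg, nfft0)
        fractal = np.median(geo, axis=0).astype(np.float64)
    else:
        geo = _irasa_poly(x, fs, cfg, nfft0, fourier=(engine == "fourier"))
        fractal = np.median(geo, axis=0)
        mixed = _periodogram_on_grid(x, fs, cfg, nfft0)[..., _band_slice(cfg)]
    return cfg.band_freqs(), mixed, fractal


def irasa_decompose(
    epoch: np.ndarray,
    fs: float,
    cfg: IrasaConfig | None = None,
    engine: str = "poly",
) -> SpectrumSet:
    """Decompose one epoch (channels x samples) into mixed, fractal, and
    oscillatory spectra on the [f_min, f_max] grid."""
    cfg = cfg or IrasaConfig()
    freqs, mixed, fractal = irasa_batch(epoch, fs, cfg, engine=engine)
    return SpectrumSet(freqs=freqs, mixed=mixed, fractal=fractal)
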