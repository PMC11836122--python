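"""Sliding-window spectral-slope time series and per-subject features.

The 30-s analysis segment is cut into 8-s windows with 75% overlap (12
windows). Each window's fractal spectrum (IRASA) is fitted by OLS of
log10(power) on log10(frequency) separately in a low (1-4 Hz), high
(20-45 Hz), and broadband control (1-45 Hz) range; the 4-20 Hz gap is never
fitted. Slopes are reported as absolute values (beta), so larger beta means
a steeper spectrum. Channel slopes are averaged within resting-state
networks per window, and each subject is summarized by the temporal mean
mu(.) and sample standard deviation sigma(.) of every network x band
series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import InvalidArgumentError, InvalidDataError, Recording
from .irasa import IrasaConfig, irasa_batch


@dataclass(frozen=True)
class BandDef:
    """A slope-fitting band, edges inclusive."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise InvalidArgumentError("need 0 < f_low < f_high")


#: lo and hi exclude the 4-20 Hz gap; bb is the broadband control fit.
DEFAULT_BANDS: tuple[BandDef, ...] = (
    BandDef("lo", 1.0, 4.0),
    BandDef("hi", 20.0, 45.0),
    BandDef("bb", 1.0, 45.0),
)


@dataclass
class SlopeSeries:
    """Per-channel, per-window, per-band slope estimates.

    beta is the absolute value of the fitted log-log slope; intercept is in
    log10(uV^2/Hz) units.
    """

    subject_id: str
    channel_labels: list[str]
    band_names: list[str]
    window_starts: np.ndarray  # seconds
    beta: np.ndarray  # (n_channels, n_windows, n_bands)
    intercept: np.ndarray
    r_squared: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.beta.shape[1]


@dataclass
class RSNSeries:
    """RSN-averaged slope series (networks x windows x bands)."""

    subject_id: str
    networks: list[str]
    band_names: list[str]
    window_starts: np.ndarray
    beta: np.ndarray


@dataclass
class SubjectFeatures:
    """Temporal mean and SD per network x band for one subject."""

    subject_id: str
    networks: list[str]
    band_names: list[str]
    mu: np.ndarray  # (n_networks, n_bands)
    sigma: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, net in enumerate(self.networks):
            for j, band in enumerate(self.band_names):
                rows.append(
                    dict(
                        subject_id=self.subject_id,
                        network=net,
                        band=band,
                        mu=self.mu[i, j],
                        sigma=self.sigma[i, j],
                    )
                )
        return pd.DataFrame(rows)


def segment_windows(
    total: float, window: float, overlap: float
) -> list[tuple[float, float]]:
    """Sliding-window positions (start, end) in seconds.

    step = window * (1 - overlap); the count is floor((total - window)/step)
    + 1, so a trailing remainder shorter than one step is left unanalyzed.
    """
    if not 0 <= overlap < 1:
        raise InvalidArgumentError("overlap must be in [0, 1)")
    if window <= 0:
        raise InvalidArgumentError("window must be positive")
    if window > total:
        raise InvalidArgumentError(
            f"window of {window} s exceeds segment of {total} s"
        )
    step = window * (1.0 - overlap)
    count = int(np.floor((total - window) / step + 1e-9)) + 1
    return [(i * step, i * step + window) for i in range(count)]


def fit_spectral_slope(
    freqs: np.ndarray, fractal_power: np.ndarray, band: BandDef
) -> tuple[float, float, float]:
    """OLS fit of log10(power) on log10(frequency) over in-band bins.

    Returns (beta, intercept, r_squared) with beta = |slope| by convention.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(fractal_power, dtype=float)
    mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
    if mask.sum() < 3:
        raise InvalidArgumentError(
            f"fewer than 3 frequency bins inside [{band.f_low}, {band.f_high}]"
        )
    p = power[..., mask]
    if np.any(p <= 0):
        raise InvalidDataError("non-positive fractal power inside fitting band")
    slope, icept, r2 = _ols_loglog(np.log10(freqs[mask]), np.log10(p))
    return float(abs(slope)), float(icept), float(r2)


def _ols_loglog(lx: np.ndarray, ly: np.ndarray):
    """Vectorized simple OLS of ly (..., n) on lx (n,)."""
    xd = lx - lx.mean()
    ym = ly.mean(axis=-1, keepdims=True)
    yd = ly - ym
    sxx = (xd * xd).sum()
    slope = (yd * xd).sum(axis=-1) / sxx
    icept = ym[..., 0] - slope * lx.mean()
    ss_res = (yd * yd).sum(axis=-1) - slope**2 * sxx
    ss_tot = (yd * yd).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return slope, icept, np.clip(r2, 0.0, 1.0)


def slope_timeseries(
    rec: Recording,
    icfg: IrasaConfig | None = None,
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    window: float = 8.0,
    overlap: float = 0.75,
    engine: str = "poly",
) -> SlopeSeries:
    """Windowed IRASA + band-wise slope fits for a preprocessed recording.

    All windows and channels are decomposed in one batched IRASA call.
    """
    icfg = icfg or IrasaConfig()
    wins = segment_windows(rec.duration, window, overlap)
    wlen = int(round(window * rec.fs))
    n_ch = rec.n_channels
    starts = np.array([int(round(s * rec.fs)) for s, _ in wins])
    # (n_ch * n_win, wlen) stack: channel-major, window-minor
    epochs = np.empty((n_ch * len(wins), wlen))
    idx = 0
    for c in range(n_ch):
        for s0 in starts:
            epochs[idx] = rec.data[c, s0 : s0 + wlen]
            idx += 1
    freqs, _, fractal = irasa_batch(epochs, rec.fs, icfg, engine=engine)
    if np.any(fractal <= 0):
        raise InvalidDataError("non-positive fractal power encountered")
    lf = np.log10(freqs)
    lp = np.log10(fractal)
    n_win, n_band = len(wins), len(bands)
    beta = np.empty((n_ch, n_win, n_band))
    icept = np.empty_like(beta)
    r2 = np.empty_like(beta)
    for j, band in enumerate(bands):
        mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
        if mask.sum() < 3:
            raise InvalidArgumentError(f"band {band.name}: fewer than 3 bins")
        s, ic, r = _ols_loglog(lf[mask], lp[:, mask])
        beta[:, :, j] = np.abs(s).reshape(n_ch, n_win)
        icept[:, :, j] = ic.reshape(n_ch, n_win)
        r2[:, :, j] = r.reshape(n_ch, n_win)
    return SlopeSeries(
        subject_id=rec.subject_id,
        channel_labels=list(rec.channel_labels),
        band_names=[b.name for b in bands],
        window_starts=np.array([s for s, _ in wins]),
        beta=beta,
        intercept=icept,
        r_squared=r2,
    )


def aggregate_rsn(
    series: SlopeSeries,
    rsn_map: dict[str, str],
    networks: list[str] | None = None,
) -> RSNSeries:
    """Average channel slopes within resting-state networks, per window.

    Channels absent from the map are dropped with a warning. By default the
    output covers every network with at least one member channel in the
    series; if ``networks`` is given explicitly, a requested network with no
    member channels is an error.
    """
    rsn_map = {k.upper(): v.upper() for k, v in rsn_map.items()}
    unmapped = [c for c in series.channel_labels if c not in rsn_map]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} channel(s) absent from RSN map: "
            + ", ".join(unmapped)
        )
    members: dict[str, list[int]] = {}
    for i, ch in enumerate(series.channel_labels):
        if ch in rsn_map:
            members.setdefault(rsn_map[ch], []).append(i)
    if networks is None:
        networks = [n for n in dict.fromkeys(rsn_map.values()) if n in members]
        if not networks:
            raise InvalidDataError("no channel of the series is mapped to any RSN")
    else:
        empty = [n for n in networks if not members.get(n)]
        if empty:
            raise InvalidDataError(
                f"requested network(s) with zero member channels: {empty}"
            )
    beta = np.stack(
        [series.beta[members[n]].mean(axis=0) for n in networks], axis=0
    )
    return RSNSeries(
        subject_id=series.subject_id,
        networks=list(networks),
        band_names=list(series.band_names),
        window_starts=series.window_starts,
        beta=beta,
    )


def temporal_summary(rsn_series: RSNSeries) -> SubjectFeatures:
    """mu = mean over windows, sigma = sample SD (n-1) over windows."""
    if rsn_series.beta.shape[1] < 2:
        raise InvalidArgumentError(
            "temporal SD needs at least 2 windows"
        )
    return SubjectFeatures(
        subject_id=rsn_series.subject_id,
        networks=list(rsn_series.networks),
        band_names=list(rsn_series.band_names),
        mu=rsn_series.beta.mean(axis=1),
        sigma=rsn_series.beta.std(axis=1, ddof=1),
    )
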