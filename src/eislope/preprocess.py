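"""Preprocessing chain: channel removal, resampling, filtering, referencing.

The chain reproduces a standard clinical-EEG cleaning recipe: drop
predesignated bad channels and the mastoids, downsample to 256 Hz (with
anti-alias filtering), band-pass 0.5-100 Hz with a 4th-order Butterworth
applied forward-backward (zero phase, effectively 8th-order magnitude),
notch out the 50 Hz mains and its harmonics, re-reference to the common
average, and pick a random contiguous 30-s epoch. Notch frequencies at or
above the post-resampling Nyquist are skipped with a warning (a 150 Hz
notch cannot apply to 256 Hz data). ICA-based artifact removal is outside
this package; ``ica_hook`` accepts an externally cleaned recording.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

from .core import (
    InsufficientDataError,
    InvalidArgumentError,
    Recording,
)
from .montage import DEFAULT_DROP

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 256.0
    bandpass: tuple[float, float] = (0.5, 100.0)
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0)
    filter_order: int = 4
    notch_q: float = 30.0
    drop_channels: tuple[str, ...] = DEFAULT_DROP
    epoch_seconds: float = 30.0
    epoch_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise InvalidArgumentError("bandpass low must satisfy 0 < low < high")
        if self.target_fs <= 2 * 45.0:
            raise InvalidArgumentError(
                "target_fs must exceed twice the 45 Hz analysis-band edge"
            )
        if self.filter_order < 1:
            raise InvalidArgumentError("filter_order must be >= 1")


def remove_channels(rec: Recording, drop: list[str] | tuple[str, ...]) -> Recording:
    """Drop channels by label (case-insensitive), preserving order.

    Unknown labels are ignored with a logged warning; removing every
    channel is an error.
    """
    dropset = {d.upper() for d in drop}
    unknown = dropset - set(rec.channel_labels)
    if unknown:
        log.warning("labels not in recording, ignored: %s", sorted(unknown))
    keep = [i for i, c in enumerate(rec.channel_labels) if c not in dropset]
    if not keep:
        raise InvalidArgumentError("channel removal would leave no channels")
    return rec.copy_with(
        data=rec.data[keep],
        channel_labels=[rec.channel_labels[i] for i in keep],
    )


def resample_and_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Downsample to cfg.target_fs, band-pass, and notch-filter.

    All filters are zero-phase (forward-backward application); the
    resampler's polyphase FIR provides anti-aliasing before decimation.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.target_fs > rec.fs:
        raise InvalidArgumentError(
            f"target_fs {cfg.target_fs} exceeds recording fs {rec.fs}"
        )
    data = rec.data
    fs = rec.fs
    if cfg.target_fs != fs:
        frac = Fraction(cfg.target_fs / fs).limit_denominator(1000)
        if abs(fs * frac - cfg.target_fs) > 1e-6:
            raise InvalidArgumentError(
                f"cannot express {cfg.target_fs}/{fs} as a small rational"
            )
        data = _sig.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        fs = cfg.target_fs
    nyq = fs / 2.0
    lo, hi = cfg.bandpass
    if hi >= nyq:
        raise InvalidArgumentError(
            f"bandpass upper edge {hi} Hz >= Nyquist {nyq} Hz after resampling"
        )
    sos = _sig.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    data = _sig.sosfiltfilt(sos, data, axis=-1)
    for f0 in cfg.notch_freqs:
        if f0 >= nyq:
            log.warning(
                "notch at %g Hz is at/above the %g Hz Nyquist; skipped", f0, nyq
            )
            continue
        b, a = _sig.iirnotch(f0, cfg.notch_q, fs=fs)
        data = _sig.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data, fs=fs)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise InvalidArgumentError("common average reference needs >= 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def select_epoch(rec: Recording, seconds: float, seed: int) -> Recording:
    """Extract a random contiguous epoch of the given duration.

    The start sample is drawn uniformly over valid positions; fixed seed,
    fixed choice.
    """
    need = int(round(seconds * rec.fs))
    if need > rec.n_samples:
        raise InsufficientDataError(
            f"recording of {rec.duration:.1f} s is "
            f"{(need - rec.n_samples) / rec.fs:.1f} s shorter than the "
            f"requested {seconds:g} s epoch"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, rec.n_samples - need + 1))
    return rec.copy_with(data=rec.data[:, start : start + need].copy())


def ica_hook(rec: Recording, cleaned: Recording | None = None) -> Recording:
    """Pass-through hook for externally ICA/MARA-cleaned data.

    Component classification is out of scope here; when a cleaned recording
    is supplied it replaces the input (labels must match), otherwise the
    input is returned untouched.
    """
    if cleaned is None:
        return rec
    if cleaned.channel_labels != rec.channel_labels:
        raise InvalidArgumentError("cleaned recording has different channels")
    return cleaned


def preprocess(
    rec: Recording,
    cfg: PreprocessConfig | None = None,
    cleaned: Recording | None = None,
) -> Recording:
    """Full chain: drop channels, resample+filter, ICA hook, CAR, epoch."""
    cfg = cfg or PreprocessConfig()
    rec = remove_channels(rec, cfg.drop_channels)
    rec = resample_and_filter(rec, cfg)
    rec = ica_hook(rec, cleaned)
    rec = common_average_reference(rec)
    rec = select_epoch(rec, cfg.epoch_seconds, cfg.epoch_seed)
    if not np.isfinite(rec.data).all():
        raise InvalidArgumentError("non-finite samples after preprocessing")
    return rec
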