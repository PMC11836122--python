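"""Recording and result I/O.

EDF support is a deliberately small, dependency-free implementation of the
plain 16-bit EDF layout (one data record per second), sufficient for
round-tripping synthetic recordings. BrainVision and FIF readers delegate
to ``mne`` when it is installed; it is an optional extra, not a hard
dependency.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, InvalidDataError, Recording

log = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_str(v: float) -> str:
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.3g}"
    return s[:8]


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as plain 16-bit EDF (µV, 1-s data records).

    Requires an integer sampling rate and an integer number of seconds;
    amplitude resolution is the 16-bit quantization of each channel's
    physical range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise InvalidArgumentError(
            "EDF writer requires a whole number of seconds of data"
        )
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    phys_min_s, phys_max_s, scaled = [], [], []
    for ch in rec.data:
        amax = float(np.max(np.abs(ch))) or 1.0
        smin, smax = _phys_str(-amax), _phys_str(amax)
        pmin, pmax = float(smin), float(smax)
        gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
        dig = np.round((ch - pmin) / gain).astype(np.int64) + _DIG_MIN
        scaled.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        phys_min_s.append(smin)
        phys_max_s.append(smax)

    head = b"".join(
        [
            _fixed("0", 8),
            _fixed(rec.subject_id or "X", 80),
            _fixed(rec.group or "", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_fixed(c, 16) for c in rec.channel_labels),
            b"".join(_fixed("", 80) for _ in range(ns)),
            b"".join(_fixed("uV", 8) for _ in range(ns)),
            b"".join(_fixed(s, 8) for s in phys_min_s),
            b"".join(_fixed(s, 8) for s in phys_max_s),
            b"".join(_fixed(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_fixed(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_fixed("", 80) for _ in range(ns)),
            b"".join(_fixed(str(fs), 8) for _ in range(ns)),
            b"".join(_fixed("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head + sig)
        for r in range(n_records):
            for c in range(ns):
                fh.write(scaled[c][r * fs : (r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read a plain 16-bit EDF file into a Recording (µV)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise InvalidDataError(f"{path} is not an EDF file (truncated header)")

    def take(off, width):
        return raw[off : off + width].decode("ascii", "replace").strip()

    subject = take(8, 80)
    group = take(88, 80)
    n_records = int(take(236, 8))
    rec_dur = float(take(244, 8))
    ns = int(take(252, 4))
    off = 256
    labels = [take(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    pmin = [float(take(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    pmax = [float(take(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dmin = [int(float(take(off + 8 * i, 8))) for i in range(ns)]
    off += 8 * ns
    dmax = [int(float(take(off + 8 * i, 8))) for i in range(ns)]
    off += 8 * ns + 80 * ns
    spr = [int(take(off + 8 * i, 8)) for i in range(ns)]
    off = 256 * (ns + 1)

    if len(set(spr)) != 1:
        raise InvalidDataError("mixed per-signal sampling rates are unsupported")
    fs = spr[0] / rec_dur
    body = np.frombuffer(raw, dtype="<i2", offset=off)
    expect = n_records * sum(spr)
    if body.size < expect:
        raise InvalidDataError(f"{path}: EDF body shorter than header promises")
    body = body[:expect].reshape(n_records, ns, spr[0]).astype(np.int64)
    data = np.empty((ns, n_records * spr[0]))
    for c in range(ns):
        gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        data[c] = (body[:, c, :].reshape(-1) - dmin[c]) * gain + pmin[c]
    return Recording(
        data=data, fs=fs, channel_labels=labels, subject_id=subject, group=group
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EEG file (EDF natively; BrainVision/FIF via optional mne).

    Channel labels are normalized to upper case and data to µV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_edf(path)
    if fmt in ("fif", "vhdr", "brainvision"):
        try:
            import mne  # optional extra
        except ImportError as exc:  # pragma: no cover - depends on env
            raise ImportError(
                f"reading {fmt} files requires the optional dependency mne "
                "(pip install eislope[io])"
            ) from exc
        reader = mne.io.read_raw_fif if fmt == "fif" else mne.io.read_raw_brainvision
        raw = reader(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data() * 1e6,  # volts -> µV
            fs=float(raw.info["sfreq"]),
            channel_labels=[c.upper() for c in raw.ch_names],
            subject_id=path.stem,
        )
    raise InvalidArgumentError(f"unsupported recording format: {fmt!r}")


def write_results(
    features: pd.DataFrame,
    stats: pd.DataFrame,
    manifest: dict,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write feature/stats CSVs and the run manifest (JSON) to outdir.

    Overwrites existing files with a warning; column order is stable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "stats": outdir / "stats.csv",
        "manifest": outdir / "manifest.json",
    }
    for p in paths.values():
        if p.exists():
            warnings.warn(f"overwriting {p}")
    features.to_csv(paths["features"], index=False)
    stats.to_csv(paths["stats"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return paths
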