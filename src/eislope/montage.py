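"""Packaged 10-10 montage and resting-state-network (RSN) channel grouping.

The acquisition montage is a 64-electrode 10-10 cap (mastoids M1/M2
included, FPz used as ground and therefore absent). Nine electrodes are
removed during preprocessing by default, leaving the 55 scalp channels the
analysis operates on; those 55 are partitioned into six RSNs (VN, SM, DA,
VAL, FP, DMN) by the packaged two-column map in ``data/rsn_map.txt``.
"""
from __future__ import annotations

from importlib import resources

from .core import InvalidDataError

#: 64-channel acquisition montage (10-10 names, mastoids included).
MONTAGE_64: tuple[str, ...] = (
    "FP1", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
    "M1", "M2",
)

#: Channels removed from every recording (bad in >10 participants, plus the
#: mastoid reference electrodes).
DEFAULT_DROP: tuple[str, ...] = (
    "AF7", "AF8", "AFZ", "F1", "F2", "TP7", "TP8", "M1", "M2",
)

#: The 55 channels retained for analysis.
RETAINED_55: tuple[str, ...] = tuple(
    c for c in MONTAGE_64 if c not in DEFAULT_DROP
)

NETWORKS: tuple[str, ...] = ("VN", "SM", "DA", "VAL", "FP", "DMN")


def load_rsn_map(path: str | None = None) -> dict[str, str]:
    """Read a two-column (channel, network) text map.

    Defaults to the packaged 55-channel map. Lines starting with ``#`` are
    comments; labels are upper-cased.
    """
    if path is None:
        text = (
            resources.files("eislope").joinpath("data/rsn_map.txt").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise InvalidDataError(f"malformed RSN map line: {line!r}")
        label, net = parts[0].upper(), parts[1].upper()
        if label in mapping:
            raise InvalidDataError(f"duplicate channel in RSN map: {label}")
        mapping[label] = net
    return mapping


def network_channels(mapping: dict[str, str] | None = None) -> dict[str, list[str]]:
    """Invert a channel->network map into network -> member channel lists."""
    mapping = load_rsn_map() if mapping is None else mapping
    out: dict[str, list[str]] = {}
    for ch, net in mapping.items():
        out.setdefault(net, []).append(ch)
    return out
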