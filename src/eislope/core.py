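"""Core containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class InvalidDataError(ValueError):
    """Input data is structurally valid but unusable (non-positive power,
    constant sample, rank-deficient design, ...)."""


class InsufficientDataError(InvalidArgumentError):
    """Recording too short for the requested operation."""


@dataclass
class Recording:
    """Multichannel EEG segment.

    data is a channels x samples matrix in microvolts; channel labels follow
    the 10-10 nomenclature (upper-cased on construction).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be channels x samples")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        self.channel_labels = [str(c).upper() for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidDataError("duplicate channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw and "meta" not in kw:
            kw["meta"] = dict(self.meta)
        return replace(self, **kw)
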