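"""Multi-channel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, LoadError
from .schedule import StimulusSchedule

#: Electrode montage used throughout: frontal-central midline plus lateral central.
DEFAULT_CHANNELS = ("Fz", "Cz", "C3", "C4")


@dataclass
class Recording:
    """EEG time series (microvolts) with its sampling rate and event schedule.

    ``data`` is shaped ``(n_channels, n_samples)``; rows follow ``channels``.
    """

    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    events: StimulusSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ArgumentError(f"fs must be > 0, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ArgumentError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        """Index of a channel, matched case-insensitively."""
        lowered = [c.lower() for c in self.channels]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise LoadError(
                f"channel {name!r} not found; available: {list(self.channels)}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """One channel's samples in microvolts."""
        return self.data[self.channel_index(name)]
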