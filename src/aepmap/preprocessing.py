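"""Filtering and stimulus-locked averaging.

Standard responses: the Cz channel is band-pass filtered (Butterworth n=4,
0.5–50 Hz, zero-phase), epoched at standard-tone onsets and averaged — over
the whole session or over its first/second half to probe response stability.
Deviant responses: channels are summed sample-wise, low-pass filtered
(Butterworth n=2, 10 Hz, zero-phase), epoched at deviant onsets and averaged.
All statistics downstream are taken on the [20, 320] ms window.

Zero-phase (forward–backward) filtering is used throughout so that extrema
latencies are not shifted by filter group delay; the effective attenuation is
the square of the single-pass response.  No baseline correction is applied:
every downstream feature is invariant to a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ArgumentError, EmptyPartError
from .recording import Recording

STANDARD_BAND_HZ = (0.5, 50.0)
STANDARD_FILTER_ORDER = 4
DEVIANT_CUTOFF_HZ = 10.0
DEVIANT_FILTER_ORDER = 2
DEFAULT_EPOCH_MS = (0.0, 500.0)
STATS_WINDOW_MS = (20.0, 320.0)


@dataclass
class AveragedResponse:
    """A stimulus-locked mean waveform on a window relative to stimulus onset."""

    t0_ms: float
    t1_ms: float
    fs: float
    values: np.ndarray
    n_epochs: int
    source_kind: str
    part: str = "whole"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = int(round((self.t1_ms - self.t0_ms) * self.fs / 1000.0)) + 1
        if len(self.values) != expected:
            raise ArgumentError(
                f"values length {len(self.values)} does not match window "
                f"[{self.t0_ms}, {self.t1_ms}] ms at fs={self.fs} (expected {expected})"
            )
        if self.n_epochs < 1:
            raise ArgumentError("n_epochs must be >= 1")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.values)) * 1000.0 / self.fs

    def __len__(self) -> int:
        return len(self.values)


def butterworth_filter(signal, fs: float, kind: str, edges, order: int):
    """Zero-phase Butterworth filtering (forward–backward, length preserving).

    ``kind`` is ``"bandpass"`` (edges = (low, high) Hz) or ``"lowpass"``
    (edges = cutoff Hz).  Edges must lie strictly inside (0, fs/2).
    """
    if order < 1:
        raise ArgumentError(f"order must be >= 1, got {order}")
    edges_arr = np.atleast_1d(np.asarray(edges, dtype=float))
    if kind == "bandpass":
        if edges_arr.shape != (2,):
            raise ArgumentError("bandpass needs two edges (low, high)")
    elif kind == "lowpass":
        if edges_arr.shape != (1,):
            raise ArgumentError("lowpass needs a single cutoff")
    else:
        raise ArgumentError(f"kind must be 'bandpass' or 'lowpass', got {kind!r}")
    if np.any(edges_arr <= 0) or np.any(edges_arr >= fs / 2.0):
        raise ArgumentError(
            f"filter edges {edges_arr.tolist()} must lie strictly inside (0, {fs / 2:g})"
        )
    sos = butter(order, edges_arr if kind == "bandpass" else edges_arr[0],
                 btype=kind, fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def _epoch_average(
    filtered: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    epoch_ms: tuple[float, float],
    reject_ptp_uv: float | None = None,
) -> tuple[np.ndarray, int]:
    """Average epochs sliced at each onset; drops epochs that leave the data."""
    i0 = int(round(epoch_ms[0] * fs / 1000.0))
    n_epoch = int(round((epoch_ms[1] - epoch_ms[0]) * fs / 1000.0)) + 1
    starts = np.round(onsets_s * fs).astype(int) + i0
    keep = (starts >= 0) & (starts + n_epoch <= len(filtered))
    starts = starts[keep]
    if len(starts) == 0:
        raise EmptyPartError("no complete epochs available for averaging")
    idx = starts[:, None] + np.arange(n_epoch)[None, :]
    epochs = filtered[idx]
    if reject_ptp_uv is not None:
        ptp = epochs.max(axis=1) - epochs.min(axis=1)
        epochs = epochs[ptp <= reject_ptp_uv]
        if len(epochs) == 0:
            raise EmptyPartError("all epochs rejected by the peak-to-peak threshold")
    return epochs.mean(axis=0), len(epochs)


def _part_mask(onsets_s: np.ndarray, session_s: float, part: str) -> np.ndarray:
    half = session_s / 2.0
    if part == "whole":
        return np.ones(len(onsets_s), dtype=bool)
    if part == "first_half":
        return onsets_s < half
    if part == "second_half":
        return onsets_s >= half
    raise ArgumentError(f"part must be whole|first_half|second_half, got {part!r}")


def average_standard(
    recording: Recording,
    channel: str = "Cz",
    epoch_ms: tuple[float, float] = DEFAULT_EPOCH_MS,
    part: str = "whole",
    band_hz: tuple[float, float] = STANDARD_BAND_HZ,
    order: int = STANDARD_FILTER_ORDER,
    reject_ptp_uv: float | None = None,
) -> AveragedResponse:
    """Average response to standard tones on one channel.

    The continuous channel is band-pass filtered, then epochs at standard
    onsets belonging to ``part`` (halves split at the session midpoint by
    onset time) are averaged elementwise.
    """
    x = butterworth_filter(recording.channel(channel), recording.fs, "bandpass",
                           band_hz, order)
    onsets = recording.events.onsets("standard")
    if len(onsets) == 0:
        raise EmptyPartError("recording has no standard events")
    onsets = onsets[_part_mask(onsets, recording.events.session_s, part)]
    if len(onsets) == 0:
        raise EmptyPartError(f"no standard events in part {part!r}")
    values, n = _epoch_average(x, recording.fs, onsets, epoch_ms, reject_ptp_uv)
    return AveragedResponse(epoch_ms[0], epoch_ms[1], recording.fs, values, n,
                            source_kind="standard", part=part)


def average_deviant(
    recording: Recording,
    channels: list[str] | str | None = None,
    epoch_ms: tuple[float, float] = DEFAULT_EPOCH_MS,
    cutoff_hz: float = DEVIANT_CUTOFF_HZ,
    order: int = DEVIANT_FILTER_ORDER,
    filter_then_epoch: bool = True,
    reject_ptp_uv: float | None = None,
) -> AveragedResponse:
    """Average response to deviant tones on the channel sum.

    ``channels`` may be a list of names, the string ``"Cz-only"`` (single
    central electrode mode), or None for all channels.  The summed continuous
    trace is low-pass filtered and then epoched/averaged; set
    ``filter_then_epoch=False`` to filter the averaged waveform instead (the
    two orders agree up to edge effects for this linear zero-phase filter).
    """
    if channels is None:
        names = list(recording.channels)
    elif isinstance(channels, str):
        if channels.lower() in ("cz-only", "cz_only", "cz"):
            names = ["Cz"]
        else:
            names = [channels]
    else:
        names = list(channels)
    summed = np.sum([recording.channel(n) for n in names], axis=0)
    onsets = recording.events.onsets("deviant")
    if len(onsets) == 0:
        raise EmptyPartError("recording has no deviant events")
    if filter_then_epoch:
        summed = butterworth_filter(summed, recording.fs, "lowpass", cutoff_hz, order)
        values, n = _epoch_average(summed, recording.fs, onsets, epoch_ms, reject_ptp_uv)
    else:
        values, n = _epoch_average(summed, recording.fs, onsets, epoch_ms, reject_ptp_uv)
        values = butterworth_filter(values, recording.fs, "lowpass", cutoff_hz, order)
    return AveragedResponse(epoch_ms[0], epoch_ms[1], recording.fs, values, n,
                            source_kind="deviant", part="whole")


def restrict_window(
    response: AveragedResponse,
    t1_ms: float = STATS_WINDOW_MS[0],
    t2_ms: float = STATS_WINDOW_MS[1],
) -> AveragedResponse:
    """Restrict a response to the closed sub-window [t1_ms, t2_ms]."""
    if not (response.t0_ms <= t1_ms <= t2_ms <= response.t1_ms):
        raise ArgumentError(
            f"[{t1_ms}, {t2_ms}] ms is not inside "
            f"[{response.t0_ms}, {response.t1_ms}] ms"
        )
    i0 = int(round((t1_ms - response.t0_ms) * response.fs / 1000.0))
    i1 = int(round((t2_ms - response.t0_ms) * response.fs / 1000.0))
    return replace(response, t0_ms=t1_ms, t1_ms=t2_ms,
                   values=response.values[i0 : i1 + 1])
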