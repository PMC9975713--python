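"""Oddball stimulation schedules.

The auditory oddball paradigm mixes frequent "standard" tones (800 Hz, 75 ms)
with rare "deviant" tones (880 Hz, 30 ms), here in an 86/14 % proportion at a
fixed stimulus-onset asynchrony (SOA).  A schedule is the timed event list a
session is built from and the ground truth downstream epoching keys off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError

STANDARD_TONE_HZ = 800.0
STANDARD_DURATION_MS = 75.0
DEVIANT_TONE_HZ = 880.0
DEVIANT_DURATION_MS = 30.0

#: Default stimulus-onset asynchrony: 75 ms standard tone + 500 ms gap.
DEFAULT_SOA_MS = 575.0
#: Default probability that any single stimulus is a deviant.
DEFAULT_P_DEVIANT = 0.14


@dataclass(frozen=True)
class StimulusEvent:
    """A single auditory stimulus.

    Parameters
    ----------
    onset_s : float
        Seconds from session start, non-negative.
    kind : str
        Either ``"standard"`` or ``"deviant"``.
    tone_hz : float
        Carrier frequency of the tone.
    duration_ms : float
        Tone duration.
    """

    onset_s: float
    kind: str
    tone_hz: float = field(default=0.0)
    duration_ms: float = field(default=0.0)

    def __post_init__(self):
        if self.onset_s < 0:
            raise ArgumentError(f"event onset must be >= 0, got {self.onset_s}")
        if self.kind not in ("standard", "deviant"):
            raise ArgumentError(f"unknown stimulus kind {self.kind!r}")
        # fill paradigm defaults when unspecified
        if self.tone_hz == 0.0:
            object.__setattr__(
                self, "tone_hz",
                STANDARD_TONE_HZ if self.kind == "standard" else DEVIANT_TONE_HZ,
            )
        if self.duration_ms == 0.0:
            object.__setattr__(
                self, "duration_ms",
                STANDARD_DURATION_MS if self.kind == "standard" else DEVIANT_DURATION_MS,
            )
        expected = (
            (STANDARD_TONE_HZ, STANDARD_DURATION_MS)
            if self.kind == "standard"
            else (DEVIANT_TONE_HZ, DEVIANT_DURATION_MS)
        )
        if (self.tone_hz, self.duration_ms) != expected:
            raise ArgumentError(
                f"{self.kind} stimulus must be {expected[0]:g} Hz / {expected[1]:g} ms, "
                f"got {self.tone_hz:g} Hz / {self.duration_ms:g} ms"
            )


@dataclass(frozen=True)
class StimulusSchedule:
    """An ordered sequence of stimuli within a session of ``session_s`` seconds."""

    events: tuple[StimulusEvent, ...]
    session_s: float

    def __post_init__(self):
        onsets = [e.onset_s for e in self.events]
        if any(o >= self.session_s for o in onsets):
            raise ArgumentError("all event onsets must lie inside the session")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ArgumentError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, kind: str | None = None) -> np.ndarray:
        """Onset times in seconds, optionally restricted to one stimulus kind."""
        return np.array(
            [e.onset_s for e in self.events if kind is None or e.kind == kind]
        )

    @property
    def deviant_fraction(self) -> float:
        if not self.events:
            return float("nan")
        return sum(e.kind == "deviant" for e in self.events) / len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "tone_hz": [e.tone_hz for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        """Write the 3-column (onset_s, kind, tone_hz) schedule CSV."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, session_s: float | None = None) -> "StimulusSchedule":
        df = pd.read_csv(path)
        events = tuple(
            StimulusEvent(onset_s=float(r.onset_s), kind=str(r.kind))
            for r in df.itertuples()
        )
        if session_s is None:
            session_s = float(df.onset_s.iloc[-1]) + 1.0 if len(df) else 0.0
        return cls(events=events, session_s=session_s)


def generate_schedule(
    session_s: float,
    soa_ms: float = DEFAULT_SOA_MS,
    p_deviant: float = DEFAULT_P_DEVIANT,
    seed: int | None = None,
    forbid_repeat_deviants: bool = False,
) -> StimulusSchedule:
    """Generate an oddball schedule of ``floor(session_s*1000/soa_ms)`` stimuli.

    Events sit on a regular SOA grid; each is independently a deviant with
    probability ``p_deviant`` (optionally suppressing back-to-back deviants,
    a common oddball constraint).  The same seed reproduces the same schedule.

    Parameters
    ----------
    session_s : float
        Total session duration in seconds (> 0).
    soa_ms : float
        Stimulus-onset asynchrony, onset-to-onset, in milliseconds (> 0).
    p_deviant : float
        Per-event deviant probability in [0, 1].
    seed : int, optional
        Seed for the pseudo-random deviant placement.
    forbid_repeat_deviants : bool
        If True, an event following a deviant is forced to be standard.
    """
    if session_s <= 0:
        raise ArgumentError(f"session_s must be > 0, got {session_s}")
    if soa_ms <= 0:
        raise ArgumentError(f"soa_ms must be > 0, got {soa_ms}")
    if not 0.0 <= p_deviant <= 1.0:
        raise ArgumentError(f"p_deviant must be in [0, 1], got {p_deviant}")

    n_events = int(np.floor(session_s * 1000.0 / soa_ms))
    rng = np.random.default_rng(seed)
    is_deviant = rng.random(n_events) < p_deviant
    if forbid_repeat_deviants:
        for i in range(1, n_events):
            if is_deviant[i - 1]:
                is_deviant[i] = False
    # onsets computed in exact milliseconds first, so decimal SOAs round-trip
    # cleanly through text formats
    events = tuple(
        StimulusEvent(onset_s=(i * soa_ms) / 1000.0,
                      kind="deviant" if d else "standard")
        for i, d in enumerate(is_deviant)
    )
    return StimulusSchedule(events=events, session_s=float(session_s))
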