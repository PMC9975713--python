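"""European Data Format (EDF+) input/output.

Writing uses a small self-contained EDF+C writer (16-bit samples, one
annotation signal carrying the stimulus events as timestamped annotation
lists), so synthetic cohorts can be exported without any extra dependency.
Reading goes through MNE's EDF reader, which also serves as an independent
implementation for writer/reader round-trip checks.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .errors import ArgumentError, LoadError
from .recording import Recording
from .schedule import StimulusEvent, StimulusSchedule

logger = logging.getLogger(__name__)

#: annotation labels written for each stimulus kind, and the default reverse
#: map applied on read (configurable because exporters differ).
KIND_TO_LABEL = {"standard": "std", "deviant": "dev"}
DEFAULT_ANNOTATION_MAP = {"std": "standard", "dev": "deviant"}

_ANNOT_BYTES_PER_RECORD = 120  # fits 2+ event TALs per 1 s record


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ArgumentError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_num(x: float, width: int = 8) -> str:
    for fmt in (f"{x:g}", f"{x:.6g}", f"{x:.3f}"):
        if len(fmt) <= width:
            return fmt
    raise ArgumentError(f"cannot format {x} in {width} EDF header chars")


def write_edf(recording: Recording, path, patient_id: str = "X X X X") -> None:
    """Write a recording as EDF+C with one annotation signal.

    Samples are quantized to 16 bits over each channel's symmetric physical
    range; events land in the annotation signal as ``+onset\\x15duration`` TALs
    labelled per :data:`KIND_TO_LABEL`.  The record duration is 1 s, so the
    sampling rate must be a positive integer and any trailing partial second
    of data is dropped.
    """
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise ArgumentError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(fs)
    n_records = recording.n_samples // fs
    if n_records == 0:
        raise ArgumentError("recording shorter than one 1 s data record")
    n_signals = len(recording.channels) + 1

    data = recording.data[:, : n_records * fs]
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6)
    # round the range up to keep header fields short and quantization symmetric
    phys_max = np.array([float(_fmt_num(np.ceil(m * 10) / 10)) for m in phys_max])
    digital = np.round(data / phys_max[:, None] * 32767).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(patient_id, 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (n_signals + 1), 8),
            _ascii_field("EDF+C", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_signals, 4),
        ]
    )
    labels = [f"EEG {ch}" for ch in recording.channels] + ["EDF Annotations"]
    annot_samples = _ANNOT_BYTES_PER_RECORD // 2
    per_signal = {
        "label": [_ascii_field(l, 16) for l in labels],
        "transducer": [_ascii_field("AgAgCl electrode", 80)] * len(recording.channels)
        + [_ascii_field("", 80)],
        "dim": [_ascii_field("uV", 8)] * len(recording.channels) + [_ascii_field("", 8)],
        "pmin": [_ascii_field(_fmt_num(-m), 8) for m in phys_max]
        + [_ascii_field(-1, 8)],
        "pmax": [_ascii_field(_fmt_num(m), 8) for m in phys_max]
        + [_ascii_field(1, 8)],
        "dmin": [_ascii_field(-32767, 8)] * len(recording.channels)
        + [_ascii_field(-32768, 8)],
        "dmax": [_ascii_field(32767, 8)] * (n_signals - 1) + [_ascii_field(32767, 8)],
        "prefilter": [_ascii_field("", 80)] * n_signals,
        "ns": [_ascii_field(fs, 8)] * len(recording.channels)
        + [_ascii_field(annot_samples, 8)],
        "reserved": [_ascii_field("", 32)] * n_signals,
    }
    for key in ("label", "transducer", "dim", "pmin", "pmax", "dmin", "dmax",
                "prefilter", "ns", "reserved"):
        header += b"".join(per_signal[key])

    events_by_record: dict[int, list[StimulusEvent]] = {}
    for ev in recording.events.events:
        events_by_record.setdefault(int(ev.onset_s), []).append(ev)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            for ch_i in range(len(recording.channels)):
                fh.write(digital[ch_i, rec_i * fs : (rec_i + 1) * fs].tobytes())
            tal = f"+{rec_i}\x14\x14\x00"
            for ev in events_by_record.get(rec_i, []):
                if ev.onset_s >= n_records:
                    continue
                tal += (
                    f"+{ev.onset_s:g}\x15{ev.duration_ms / 1000.0:g}"
                    f"\x14{KIND_TO_LABEL[ev.kind]}\x14\x00"
                )
            raw = tal.encode("ascii")
            if len(raw) > _ANNOT_BYTES_PER_RECORD:
                raise ArgumentError(
                    f"too many events in record {rec_i} for the annotation signal"
                )
            fh.write(raw.ljust(_ANNOT_BYTES_PER_RECORD, b"\x00"))


def read_recording(
    path,
    annotation_map: dict[str, str] | None = None,
    require_channels: tuple[str, ...] = (),
) -> Recording:
    """Load an EDF recording via MNE and decode stimulus annotations.

    Channel names are matched case-insensitively after stripping an optional
    ``EEG `` prefix; annotation descriptions are mapped to stimulus kinds via
    ``annotation_map`` (default ``{"std": "standard", "dev": "deviant"}``);
    unmapped labels are skipped with a logged warning.
    """
    import mne

    annotation_map = dict(DEFAULT_ANNOTATION_MAP if annotation_map is None
                          else annotation_map)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise LoadError(f"cannot read EDF file {path}: {exc}") from exc

    names = []
    for name in raw.ch_names:
        clean = name[4:] if name.lower().startswith("eeg ") else name
        names.append(clean.strip())
    for wanted in require_channels:
        if wanted.lower() not in [n.lower() for n in names]:
            raise LoadError(f"EDF file {path} lacks required channel {wanted!r}")

    data_uv = raw.get_data() * 1e6  # MNE returns volts
    session_s = raw.n_times / raw.info["sfreq"]

    events, skipped = [], 0
    for onset, desc in sorted(zip(raw.annotations.onset, raw.annotations.description)):
        kind = annotation_map.get(desc)
        if kind is None:
            skipped += 1
            logger.warning("skipping unmapped annotation %r at %.3f s", desc, onset)
            continue
        events.append(StimulusEvent(onset_s=float(onset), kind=kind))
    if skipped:
        logger.warning("%d annotations had no mapping and were skipped", skipped)

    schedule = StimulusSchedule(events=tuple(events), session_s=session_s)
    return Recording(
        fs=float(raw.info["sfreq"]), channels=tuple(names), data=data_uv,
        events=schedule,
    )
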