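"""Synthetic oddball-EEG cohorts.

Emulates 20-minute auditory oddball sessions recorded at Fz/Cz/C3/C4: a
stationary colored-noise background (pink + white) plus a stimulus-locked ERP
template added at every event onset.  Two patient classes are modelled:

``good``
    A stable, high-amplitude evoked response: the same multi-component
    template throughout the session, so the split-half similarity of the
    standard average is high and the deviant average keeps a large total
    oscillation.
``bad``
    An attenuated response (``snr_bad``), per-trial latency jitter, and a
    morphology drift between the first and second half of the session
    (``similarity_drift_bad``), degrading both stability and amplitude — the
    phenomenology of a poorly reactive, disorganized cortical response.

SNR values are peak template amplitude expressed in units of the 2 µV
reference background RMS, so the ERP survives when noise is switched off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ArgumentError
from .recording import DEFAULT_CHANNELS, Recording
from .schedule import (
    DEFAULT_P_DEVIANT,
    DEFAULT_SOA_MS,
    StimulusSchedule,
    generate_schedule,
)

#: Reference background RMS (µV) that SNR values are expressed against.
NOISE_REF_RMS_UV = 2.0
#: Default sampling rate (Hz).
DEFAULT_FS = 500.0
#: Default session length (s): the paradigm's 20-minute recording.
DEFAULT_SESSION_S = 1200.0

#: Per-channel ERP gain (frontocentral maximum at Cz, as for auditory ERPs).
CHANNEL_GAINS = {"Fz": 0.9, "Cz": 1.0, "C3": 0.85, "C4": 0.8}

# ERP templates as sums of Gaussian-windowed components (amp µV, center ms,
# width ms, presence probability) on a [0, 400] ms support, loosely shaped
# like the classical P50 / N100 / P200 (/N300) auditory sequence.  The
# obligatory mid-latency components are always expressed; the minor early and
# late ones only in a fraction of patients, as in real cohorts — this is what
# makes the discrete extrema count vary across a cohort.  Amplitudes are
# relative; the template is rescaled to the requested peak before insertion.
STANDARD_COMPONENTS = (
    (1.5, 55.0, 18.0, 0.7),
    (-5.0, 100.0, 30.0, 1.0),
    (3.5, 200.0, 45.0, 1.0),
    (-1.8, 300.0, 50.0, 0.5),
)
DEVIANT_COMPONENTS = (
    (2.0, 60.0, 18.0, 0.7),
    (-6.0, 110.0, 32.0, 1.0),
    (4.5, 210.0, 48.0, 1.0),
    (-2.5, 300.0, 55.0, 0.5),
)
# Alternative morphology the bad-class response drifts toward in the second
# half of the session: shifted latencies and flipped mid-latency polarity,
# nearly uncorrelated with the main templates.
DRIFT_COMPONENTS = (
    (-2.0, 70.0, 25.0, 1.0),
    (4.0, 150.0, 40.0, 1.0),
    (-3.0, 260.0, 50.0, 1.0),
)

TEMPLATE_SUPPORT_MS = 400.0
BAD_JITTER_SD_MS = 20.0

# Inter-patient morphology variability: each patient's template components get
# their amplitudes scaled log-normally (sd 0.2), centers shifted (sd 15 ms)
# and widths scaled (0.85–1.25), so feature values — including the discrete
# extrema count — scatter across a cohort as they do across real patients.
COMPONENT_AMP_LOGSD = 0.2
COMPONENT_CENTER_SD_MS = 15.0
COMPONENT_WIDTH_RANGE = (0.85, 1.25)


def _perturb_components(components, rng: np.random.Generator):
    out = []
    for amp, center, width, presence in components:
        expressed = rng.random() < presence
        jittered = (
            amp * rng.lognormal(0.0, COMPONENT_AMP_LOGSD),
            center + rng.normal(0.0, COMPONENT_CENTER_SD_MS),
            width * rng.uniform(*COMPONENT_WIDTH_RANGE),
        )
        if expressed:  # draws happen either way, keeping streams aligned
            out.append(jittered)
    if not out:
        out.append(components[1][:3])
    return tuple(out)


@dataclass(frozen=True)
class CohortSpec:
    """Size, signal-to-noise, and stability parameters of a synthetic cohort."""

    n_good: int = 6
    n_bad: int = 23
    snr_good: float = 3.0
    snr_bad: float = 0.4
    similarity_drift_bad: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 0 or self.n_bad < 0:
            raise ArgumentError("patient counts must be >= 0")
        if self.snr_good <= 0 or self.snr_bad <= 0:
            raise ArgumentError("snr values must be > 0")
        if not 0.0 <= self.similarity_drift_bad <= 1.0:
            raise ArgumentError("similarity_drift_bad must be in [0, 1]")


@dataclass
class SyntheticPatient:
    """A labelled synthetic recording."""

    recording: Recording
    label: str
    patient_id: str

    def __post_init__(self):
        if self.label not in ("good", "bad"):
            raise ArgumentError(f"label must be 'good' or 'bad', got {self.label!r}")
        if tuple(self.recording.channels) != DEFAULT_CHANNELS:
            raise ArgumentError(
                f"recording must carry exactly the channels {DEFAULT_CHANNELS}"
            )


def gaussian_components_template(t_ms: np.ndarray, components) -> np.ndarray:
    """Evaluate a sum of Gaussian bumps (amp, center ms, width ms) at ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    for comp in components:
        amp, center, width = comp[:3]  # a trailing presence prob is ignored
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _sampled_template(components, fs: float, peak_uv: float) -> np.ndarray:
    t_ms = np.arange(int(round(TEMPLATE_SUPPORT_MS * fs / 1000.0)) + 1) * 1000.0 / fs
    v = gaussian_components_template(t_ms, components)
    return v * (peak_uv / np.max(np.abs(v)))


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude ("pink") noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def background_noise(
    n: int,
    rng: np.random.Generator,
    rms_uv: float = NOISE_REF_RMS_UV,
    pink_white_ratio: float = 2.0,
) -> np.ndarray:
    """Stationary EEG-like background: pink + white at a given amplitude ratio."""
    if rms_uv == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    p = pink_noise(n, rng)
    # amplitude ratio pink:white = r:1 with total RMS = rms_uv
    r = pink_white_ratio
    norm = np.sqrt(1.0 + r**2)
    return rms_uv * (r * p + w) / norm


def _mixed_template(base: np.ndarray, alt: np.ndarray, drift: float, peak_uv: float) -> np.ndarray:
    """Morph ``base`` toward ``alt`` by ``drift`` and restore the peak amplitude."""
    if drift == 0:
        return base
    mix = (1.0 - drift) * base + drift * alt
    m = np.max(np.abs(mix))
    return mix * (peak_uv / m) if m > 0 else mix


def synthesize_patient(
    schedule: StimulusSchedule,
    label: str,
    spec: CohortSpec,
    fs: float = DEFAULT_FS,
    seed: int | np.random.SeedSequence | None = None,
    patient_id: str = "patient",
    noise_rms_uv: float = NOISE_REF_RMS_UV,
    pink_white_ratio: float = 2.0,
) -> SyntheticPatient:
    """Render one patient's 4-channel recording from a stimulus schedule.

    The ERP track (template inserted at each event onset, with class-dependent
    amplitude, jitter and second-half drift) is shared across channels up to a
    fixed topographic gain; background noise is independent per channel.
    """
    if fs < 200:
        raise ArgumentError(
            f"fs must be >= 200 Hz so the 20/320 ms window edges are on-grid, got {fs}"
        )
    if label not in ("good", "bad"):
        raise ArgumentError(f"label must be 'good' or 'bad', got {label!r}")
    rng = np.random.default_rng(seed)

    n_samples = int(round(schedule.session_s * fs))
    snr = spec.snr_good if label == "good" else spec.snr_bad
    peak_uv = snr * NOISE_REF_RMS_UV
    drift = 0.0 if label == "good" else spec.similarity_drift_bad
    jitter_sd_ms = 0.0 if label == "good" else BAD_JITTER_SD_MS

    templates_first = {
        "standard": _sampled_template(_perturb_components(STANDARD_COMPONENTS, rng), fs, peak_uv),
        "deviant": _sampled_template(_perturb_components(DEVIANT_COMPONENTS, rng), fs, peak_uv),
    }
    alt = {
        kind: _sampled_template(DRIFT_COMPONENTS, fs, peak_uv) for kind in templates_first
    }
    templates_second = {
        kind: _mixed_template(templates_first[kind], alt[kind], drift, peak_uv)
        for kind in templates_first
    }

    half_s = schedule.session_s / 2.0
    erp_track = np.zeros(n_samples)
    for event in schedule.events:
        tpl = (templates_first if event.onset_s < half_s else templates_second)[event.kind]
        shift_ms = rng.normal(0.0, jitter_sd_ms) if jitter_sd_ms > 0 else 0.0
        start = int(round((event.onset_s + shift_ms / 1000.0) * fs))
        stop = min(start + len(tpl), n_samples)
        if start < 0 or start >= n_samples:
            continue
        erp_track[start:stop] += tpl[: stop - start]

    data = np.empty((len(DEFAULT_CHANNELS), n_samples))
    for i, ch in enumerate(DEFAULT_CHANNELS):
        noise = background_noise(n_samples, rng, noise_rms_uv, pink_white_ratio)
        data[i] = CHANNEL_GAINS[ch] * erp_track + noise

    rec = Recording(fs=fs, channels=DEFAULT_CHANNELS, data=data, events=schedule)
    return SyntheticPatient(recording=rec, label=label, patient_id=patient_id)


def _child_seed(master: int, index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(index, stream))


def iter_cohort(
    spec: CohortSpec,
    session_s: float = DEFAULT_SESSION_S,
    soa_ms: float = DEFAULT_SOA_MS,
    p_deviant: float = DEFAULT_P_DEVIANT,
    fs: float = DEFAULT_FS,
    noise_rms_uv: float = NOISE_REF_RMS_UV,
) -> Iterator[SyntheticPatient]:
    """Lazily generate the cohort's patients (good ones first).

    Each patient gets an independent schedule and signal stream, both derived
    deterministically from ``spec.seed`` and the patient index, so cohorts are
    reproducible while patients stay independent.
    """
    if spec.n_good + spec.n_bad < 1:
        raise ArgumentError("cannot generate an empty cohort")
    labels = ["good"] * spec.n_good + ["bad"] * spec.n_bad
    for index, label in enumerate(labels):
        sched_seed = int(_child_seed(spec.seed, index, 0).generate_state(1)[0] & 0x7FFFFFFF)
        schedule = generate_schedule(session_s, soa_ms, p_deviant, seed=sched_seed)
        yield synthesize_patient(
            schedule,
            label,
            spec,
            fs=fs,
            seed=_child_seed(spec.seed, index, 1),
            patient_id=f"pt{index:02d}",
            noise_rms_uv=noise_rms_uv,
        )


def generate_cohort(spec: CohortSpec, **kwargs) -> list[SyntheticPatient]:
    """Materialize :func:`iter_cohort` as a list (memory: ~20 MB per patient)."""
    return list(iter_cohort(spec, **kwargs))
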