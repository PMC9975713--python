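"""The four ERP features and the two 2D cohort maps.

Standard map: per patient, the coordinates are (σ, r) — the standard deviation
of the whole-session standard average on [20, 320] ms and the Pearson
similarity between the first-half and second-half standard averages on the
same window.  Deviant map: (N_E, |ΔV|) — the number of interior local extrema
of the deviant average and the total oscillation, i.e. the summed absolute
differences between consecutive extrema.

Map coordinates are z-scored across the cohort (1/N variance convention), and
the transform parameters are kept so held-out patients can be projected with
training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateFeatureError, UndefinedSimilarityError
from .preprocessing import (
    STATS_WINDOW_MS,
    AveragedResponse,
    average_deviant,
    average_standard,
    restrict_window,
)
from .synth import SyntheticPatient


@dataclass(frozen=True)
class StandardFeatures:
    """σ (µV) and split-half similarity r of the standard response."""

    sigma: float
    similarity: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ArgumentError("sigma must be >= 0")
        if not -1.0 <= self.similarity <= 1.0 + 1e-12:
            raise ArgumentError("similarity must lie in [-1, 1]")


@dataclass(frozen=True)
class DeviantFeatures:
    """Extrema count N_E, total oscillation |ΔV| (µV), and extrema times (ms)."""

    n_extrema: int
    oscillation: float
    extrema_positions: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_extrema < 0 or self.oscillation < 0:
            raise ArgumentError("n_extrema and oscillation must be >= 0")
        if self.n_extrema < 2 and self.oscillation != 0:
            raise ArgumentError("oscillation must be 0 with fewer than 2 extrema")


@dataclass(frozen=True)
class FeaturePoint:
    """A patient's normalized coordinates in one of the two maps."""

    patient_id: str
    map: str  # "standard" | "deviant"
    x: float
    y: float
    label: str = "unknown"

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ArgumentError("map coordinates must be finite")


@dataclass(frozen=True)
class NormalizationParams:
    """Affine z-score transform learned on a cohort (1/N SD convention)."""

    mean: float
    sd: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def compute_std(response: AveragedResponse) -> float:
    """Standard deviation of the waveform (population 1/N convention)."""
    if len(response) < 2:
        raise ArgumentError("compute_std needs at least 2 samples")
    return float(np.std(response.values))


def compute_similarity(a: AveragedResponse, b: AveragedResponse) -> float:
    """Pearson correlation between two same-window waveforms."""
    if (a.t0_ms, a.t1_ms, len(a)) != (b.t0_ms, b.t1_ms, len(b)):
        raise ArgumentError("similarity needs responses on the same window")
    va, vb = a.values, b.values
    if np.std(va) == 0 or np.std(vb) == 0:
        raise UndefinedSimilarityError(
            "similarity is undefined for a zero-variance waveform"
        )
    return float(np.corrcoef(va, vb)[0, 1])


def detect_extrema(response: AveragedResponse):
    """Interior local extrema of a sampled waveform.

    A point is an extremum where the first difference changes sign; a run of
    equal samples (plateau) whose neighbours lie on the same side collapses to
    a single extremum at the run's midpoint.  Endpoints never count.

    Returns ``(n_extrema, positions_ms, values)``.
    """
    v = response.values
    if len(v) < 3:
        raise ArgumentError("detect_extrema needs at least 3 samples")
    # collapse runs of equal values
    run_starts = np.flatnonzero(np.r_[True, np.diff(v) != 0])
    run_ends = np.r_[run_starts[1:] - 1, len(v) - 1]
    run_vals = v[run_starts]
    positions, values = [], []
    dt_ms = 1000.0 / response.fs
    for j in range(1, len(run_vals) - 1):
        prev_v, this_v, next_v = run_vals[j - 1], run_vals[j], run_vals[j + 1]
        if (this_v > prev_v and this_v > next_v) or (this_v < prev_v and this_v < next_v):
            mid = (run_starts[j] + run_ends[j]) / 2.0
            positions.append(response.t0_ms + mid * dt_ms)
            values.append(float(this_v))
    return len(positions), tuple(positions), tuple(values)


def compute_oscillation(extrema_values: Iterable[float]) -> float:
    """|ΔV| = Σ|V(e_i) − V(e_{i+1})| over consecutive extrema; 0 if fewer than 2."""
    vals = np.asarray(list(extrema_values), dtype=float)
    if len(vals) < 2:
        return 0.0
    return float(np.sum(np.abs(np.diff(vals))))


def normalize_cohort(values) -> tuple[np.ndarray, NormalizationParams]:
    """Z-score one feature across a cohort; returns values and the transform."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ArgumentError("cohort normalization needs at least 2 patients")
    sd = float(np.std(x))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateFeatureError("feature has zero spread across the cohort")
    params = NormalizationParams(mean=float(np.mean(x)), sd=sd)
    return params.apply(x), params


def extract_standard_features(
    recording,
    channel: str = "Cz",
    epoch_ms=(0.0, 500.0),
    stats_window_ms=STATS_WINDOW_MS,
) -> StandardFeatures:
    """σ from the whole-session standard average; r between the two halves."""
    whole = restrict_window(
        average_standard(recording, channel=channel, epoch_ms=epoch_ms, part="whole"),
        *stats_window_ms,
    )
    first = restrict_window(
        average_standard(recording, channel=channel, epoch_ms=epoch_ms, part="first_half"),
        *stats_window_ms,
    )
    second = restrict_window(
        average_standard(recording, channel=channel, epoch_ms=epoch_ms, part="second_half"),
        *stats_window_ms,
    )
    return StandardFeatures(
        sigma=compute_std(whole), similarity=compute_similarity(first, second)
    )


def extract_deviant_features(
    recording,
    electrode_mode: str = "all",
    epoch_ms=(0.0, 500.0),
    stats_window_ms=STATS_WINDOW_MS,
) -> DeviantFeatures:
    """N_E and |ΔV| from the deviant average (channel sum or Cz only)."""
    channels = "Cz-only" if electrode_mode.lower() in ("cz", "cz-only", "cz_only") else None
    resp = restrict_window(
        average_deviant(recording, channels=channels, epoch_ms=epoch_ms),
        *stats_window_ms,
    )
    n, pos, vals = detect_extrema(resp)
    return DeviantFeatures(
        n_extrema=n, oscillation=compute_oscillation(vals), extrema_positions=pos
    )


def build_feature_table(
    patients: Iterable[SyntheticPatient],
    electrode_mode: str = "all",
    epoch_ms=(0.0, 500.0),
    stats_window_ms=STATS_WINDOW_MS,
) -> pd.DataFrame:
    """Raw + normalized map coordinates for a cohort.

    Returns a tidy frame with one row per (patient, map) and columns
    patient_id, map, raw_x, raw_y, norm_x, norm_y, label.  Standard-map
    features always come from Cz; the electrode mode governs the deviant sum.
    """
    rows = []
    for patient in patients:
        rec = getattr(patient, "recording", patient)
        pid = getattr(patient, "patient_id", "unknown")
        label = getattr(patient, "label", "unknown")
        try:
            std = extract_standard_features(rec, epoch_ms=epoch_ms,
                                            stats_window_ms=stats_window_ms)
            dev = extract_deviant_features(rec, electrode_mode=electrode_mode,
                                           epoch_ms=epoch_ms,
                                           stats_window_ms=stats_window_ms)
        except Exception as exc:
            raise type(exc)(f"patient {pid!r}: {exc}") from exc
        rows.append((pid, "standard", std.sigma, std.similarity, label))
        rows.append((pid, "deviant", float(dev.n_extrema), dev.oscillation, label))
    if not rows:
        raise ArgumentError("empty cohort")
    df = pd.DataFrame(rows, columns=["patient_id", "map", "raw_x", "raw_y", "label"])
    for map_name in ("standard", "deviant"):
        mask = df["map"] == map_name
        for raw, norm in (("raw_x", "norm_x"), ("raw_y", "norm_y")):
            normed, _ = normalize_cohort(df.loc[mask, raw].to_numpy())
            df.loc[mask, norm] = normed
    return df[["patient_id", "map", "raw_x", "raw_y", "norm_x", "norm_y", "label"]]


def build_maps(
    patients: Iterable[SyntheticPatient], **kwargs
) -> tuple[list[FeaturePoint], list[FeaturePoint]]:
    """Cohort-normalized standard-map and deviant-map points."""
    df = build_feature_table(patients, **kwargs)
    points = {"standard": [], "deviant": []}
    for row in df.itertuples():
        points[row.map].append(
            FeaturePoint(patient_id=row.patient_id, map=row.map,
                         x=row.norm_x, y=row.norm_y, label=row.label)
        )
    return points["standard"], points["deviant"]


def map_arrays(df: pd.DataFrame, map_name: str):
    """(X, y, patient_ids) arrays of one map from a feature table (raw coords)."""
    sub = df[df["map"] == map_name]
    X = sub[["raw_x", "raw_y"]].to_numpy(dtype=float)
    y = sub["label"].to_numpy()
    return X, y, sub["patient_id"].to_numpy()
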