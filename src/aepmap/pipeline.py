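"""End-to-end orchestration: simulate/ingest → features → maps → LOO → report.

The report bundle written by :func:`run_pipeline` contains:

``features.csv``
    the cohort feature table (raw and normalized coordinates, both maps);
``loo_report.csv``
    per patient: the fold probabilities from the default standard-map and
    deviant-map classifiers, the combined min-decision, prediction and score;
``summary.json``
    confusion matrices and (accuracy, sensitivity, specificity) for every
    classifier on both maps plus the combined decision, and the config hash;
``grid_<map>_<classifier>.csv`` / ``map_<map>_<classifier>.png``
    posterior grids of the cohort-fitted classifiers.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .classifiers import (
    GaussianMapClassifier,
    KNeighborsMapClassifier,
    RbfSvmMapClassifier,
    probability_grid,
)
from .edf import read_recording, write_edf
from .errors import ArgumentError, UndefinedMetricError
from .evaluation import combined_loo, leave_one_out, metrics
from .features import build_feature_table, map_arrays, normalize_cohort
from .plotting import plot_probability_map
from .synth import CohortSpec, iter_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; mirrors the CLI flags and the TOML file."""

    # synthetic cohort
    n_good: int = 6
    n_bad: int = 23
    snr_good: float = 3.0
    snr_bad: float = 0.4
    similarity_drift_bad: float = 0.8
    session_s: float = 1200.0
    soa_ms: float = 575.0
    p_deviant: float = 0.14
    fs: float = 500.0
    # windows
    epoch_ms: tuple[float, float] = (0.0, 500.0)
    stats_window_ms: tuple[float, float] = (20.0, 320.0)
    # electrodes: "all" (4-channel deviant sum) or "cz-only"
    electrode_mode: str = "all"
    # classifiers
    k: int = 4
    gamma: float = 1.0
    c_penalty: float = 10.0
    # probability grid
    grid_bounds: tuple[float, float, float, float] = (-3.0, 3.0, -3.0, 3.0)
    grid_step: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.electrode_mode.lower() not in ("all", "cz-only", "cz_only", "cz"):
            raise ArgumentError(f"unknown electrode_mode {self.electrode_mode!r}")
        if self.grid_step <= 0:
            raise ArgumentError("grid_step must be > 0")
        # delegate the remaining validation to the owning modules
        self.cohort_spec()

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_good=self.n_good, n_bad=self.n_bad, snr_good=self.snr_good,
            snr_bad=self.snr_bad, similarity_drift_bad=self.similarity_drift_bad,
            seed=self.seed,
        )

    @classmethod
    def from_toml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        with open(path, "rb") as fh:
            payload = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in (overrides or {}).items() if v is not None})
        for key in ("epoch_ms", "stats_window_ms", "grid_bounds"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def classifier_suite(config: PipelineConfig) -> dict:
    return {
        "gaussian": GaussianMapClassifier(),
        "knn": KNeighborsMapClassifier(n_neighbors=config.k),
        "weighted_knn": KNeighborsMapClassifier(n_neighbors=config.k, weighted=True),
        "svm": RbfSvmMapClassifier(gamma=config.gamma, c_penalty=config.c_penalty),
    }


def load_cohort_from_edf(input_dir, annotation_map=None) -> list[SimpleNamespace]:
    """Read every ``*.edf`` in a directory; labels come from ``labels.csv``
    (columns patient_id,label; patient_id = file stem) when present."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.edf"))
    if not paths:
        raise ArgumentError(f"no EDF files found in {input_dir}")
    labels = {}
    labels_csv = input_dir / "labels.csv"
    if labels_csv.exists():
        df = pd.read_csv(labels_csv)
        labels = dict(zip(df["patient_id"].astype(str), df["label"].astype(str)))
    cohort = []
    for p in paths:
        rec = read_recording(p, annotation_map=annotation_map)
        cohort.append(
            SimpleNamespace(
                recording=rec,
                patient_id=p.stem,
                label=labels.get(p.stem, "unknown"),
            )
        )
    return cohort


def simulate_to_dir(config: PipelineConfig, out_dir) -> list[Path]:
    """Write the synthetic cohort as one EDF per patient plus labels.csv and
    per-patient schedule CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written, rows = [], []
    for patient in iter_cohort(
        config.cohort_spec(), session_s=config.session_s, soa_ms=config.soa_ms,
        p_deviant=config.p_deviant, fs=config.fs,
    ):
        path = out_dir / f"{patient.patient_id}.edf"
        write_edf(patient.recording, path)
        patient.recording.events.to_csv(out_dir / f"{patient.patient_id}_schedule.csv")
        rows.append({"patient_id": patient.patient_id, "label": patient.label})
        written.append(path)
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    return written


def _safe_metrics(cm) -> dict:
    try:
        acc, sens, spec = metrics(cm)
    except UndefinedMetricError:
        acc = sens = spec = None
    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "accuracy": acc, "sensitivity": sens, "specificity": spec,
    }


def run_pipeline(config: PipelineConfig, out_dir, input_dir=None) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    With ``input_dir`` the cohort is read from EDF files there; otherwise a
    synthetic cohort is generated from the config.  Returns the summary dict
    (also written as ``summary.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config %s (hash %s)", config, config.hash())

    if input_dir is not None:
        cohort = load_cohort_from_edf(input_dir)
    else:
        cohort = iter_cohort(
            config.cohort_spec(), session_s=config.session_s, soa_ms=config.soa_ms,
            p_deviant=config.p_deviant, fs=config.fs,
        )
    table = build_feature_table(
        cohort, electrode_mode=config.electrode_mode, epoch_ms=config.epoch_ms,
        stats_window_ms=config.stats_window_ms,
    )
    table.to_csv(out_dir / "features.csv", index=False)

    suite = classifier_suite(config)
    summary: dict = {"config_hash": config.hash(), "electrode_mode": config.electrode_mode,
                     "maps": {}}
    map_data = {m: map_arrays(table, m) for m in ("standard", "deviant")}
    for map_name, (X, y, ids) in map_data.items():
        per_clf = {}
        for name, clf in suite.items():
            res = leave_one_out(X, y, clf, ids)
            per_clf[name] = {"loo_score": res.score, **_safe_metrics(res.confusion)}
        summary["maps"][map_name] = per_clf

    # combined min-decision with the default pairing:
    # unweighted kNN on the standard map, weighted kNN on the deviant map
    (Xs, ys, ids), (Xd, yd, _) = map_data["standard"], map_data["deviant"]
    res_std, res_dev, res_comb = combined_loo(
        Xs, Xd, ys, suite["knn"], suite["weighted_knn"], patient_ids=ids,
    )
    report = pd.DataFrame(
        {
            "patient_id": res_std.per_patient["patient_id"],
            "fold_probability_standard": res_std.per_patient["probability"],
            "fold_probability_deviant": res_dev.per_patient["probability"],
            "p_dec": res_comb.per_patient["probability"],
            "predicted": res_comb.per_patient["predicted"],
            "label": res_comb.per_patient["label"],
            "s_i": res_comb.per_patient["s_i"],
        }
    )
    report.to_csv(out_dir / "loo_report.csv", index=False)
    summary["combined"] = {"loo_score": res_comb.score, **_safe_metrics(res_comb.confusion)}

    # posterior grids of the cohort-fitted classifiers
    for map_name, (X, y, ids) in map_data.items():
        Xn = np.column_stack([normalize_cohort(X[:, j])[0] for j in range(X.shape[1])])
        for name, clf in suite.items():
            model = clf.fit(Xn, y)
            grid = probability_grid(model, bounds=config.grid_bounds,
                                    step=config.grid_step)
            grid.to_csv(out_dir / f"grid_{map_name}_{name}.csv")
            plot_probability_map(
                grid, Xn, y, title=f"{map_name} map — {name}",
                path=out_dir / f"map_{map_name}_{name}.png",
            )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
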