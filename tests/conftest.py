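import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aepmap import CohortSpec, build_feature_table, iter_cohort
from aepmap.preprocessing import AveragedResponse

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: study-condition cohort: 6 good / 23 bad patients, snr 3 vs 0.4, drift 0.8
N_SEEDS = 20


def make_response(values, fs=500.0, t0_ms=0.0, kind="standard", part="whole",
                  n_epochs=1):
    """AveragedResponse wrapper around an arbitrary sample sequence."""
    values = np.asarray(values, dtype=float)
    t1_ms = t0_ms + (len(values) - 1) * 1000.0 / fs
    return AveragedResponse(t0_ms=t0_ms, t1_ms=t1_ms, fs=fs, values=values,
                            n_epochs=n_epochs, source_kind=kind, part=part)


@pytest.fixture(scope="session")
def clustered_cohort_tables() -> list[pd.DataFrame]:
    """Feature tables of 20 seeded 6/23 cohorts under the study conditions.

    Generated once per session and shared by the generator-separation,
    map-clustering and cross-validated-recovery tests (full 20-minute
    sessions at 500 Hz; ~2 min of compute).
    """
    tables = []
    for seed in range(1, N_SEEDS + 1):
        spec = CohortSpec(n_good=6, n_bad=23, snr_good=3.0, snr_bad=0.4,
                          similarity_drift_bad=0.8, seed=seed)
        tables.append(build_feature_table(iter_cohort(spec)))
    return tables


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    """A fast 3/5 cohort (2-minute sessions, 250 Hz) for smoke-level checks."""
    spec = CohortSpec(n_good=3, n_bad=5, seed=42)
    return build_feature_table(iter_cohort(spec, session_s=120.0, fs=250.0))
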