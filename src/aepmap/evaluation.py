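"""Cross-validation, confusion metrics, combined decision, Fisher exact test.

Leave-one-out is run on *raw* map coordinates: for every fold the z-score
normalization and the classifier are refitted on the n−1 training patients
and the held-out point is projected with the training statistics, so no
cohort information leaks into the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import clone

from .errors import ArgumentError, FoldError, UndefinedMetricError
from .features import normalize_cohort

POSITIVE_LABEL = "good"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 confusion counts with positive = good neurological outcome."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ArgumentError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=POSITIVE_LABEL):
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of a confusion matrix."""
    if cm.n == 0 or cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError(
            f"metrics undefined for counts tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}"
        )
    return (
        (cm.tp + cm.tn) / cm.n,
        cm.tp / (cm.tp + cm.fn),
        cm.tn / (cm.tn + cm.fp),
    )


@dataclass
class LooResult:
    """Leave-one-out outcome: per-patient report, mean score, confusion."""

    per_patient: pd.DataFrame  # patient_id, probability, predicted, label, s_i
    score: float
    confusion: ConfusionMatrix

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ArgumentError("score must lie in [0, 1]")


def leave_one_out(X_raw, y, classifier, patient_ids=None) -> LooResult:
    """LOO cross-validation of one map.

    ``X_raw`` holds raw (unnormalized) 2D feature coordinates; each fold
    refits the per-feature z-score on its training patients before fitting a
    clone of ``classifier``.  The per-patient score is 1 iff the thresholded
    prediction matches the label; the aggregate score is their mean, which
    equals the confusion-matrix accuracy by construction.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y)
    n = len(X_raw)
    if n < 3:
        raise ArgumentError("leave-one-out needs at least 3 patients")
    if patient_ids is None:
        patient_ids = np.array([f"p{i}" for i in range(n)])
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise FoldError(
                f"training set for held-out patient {patient_ids[i]!r} lost a class",
                patient_id=str(patient_ids[i]),
            )
        X_train = np.empty_like(X_raw[mask])
        x_test = np.empty(X_raw.shape[1])
        for j in range(X_raw.shape[1]):
            X_train[:, j], params = normalize_cohort(X_raw[mask, j])
            x_test[j] = params.apply(X_raw[i, j])
        model = clone(classifier).fit(X_train, y_train)
        p = float(model.p_good([x_test])[0])
        predicted = POSITIVE_LABEL if p > 0.5 else "bad"
        rows.append(
            {
                "patient_id": patient_ids[i],
                "probability": p,
                "predicted": predicted,
                "label": y[i],
                "s_i": int(predicted == y[i]),
            }
        )
    report = pd.DataFrame(rows)
    cm = ConfusionMatrix.from_predictions(report["label"], report["predicted"])
    return LooResult(per_patient=report, score=float(report["s_i"].mean()), confusion=cm)


def combine_decision(p_standard: float, p_deviant: float) -> float:
    """Combined decision probability: the minimum of the two map posteriors.

    Taking the minimum is conservative toward the "bad" call — a patient is
    predicted good only if *both* maps agree — and therefore can never add
    false positives relative to either input classifier.
    """
    for name, p in (("p_standard", p_standard), ("p_deviant", p_deviant)):
        if not (np.isfinite(p) and 0.0 <= p <= 1.0):
            raise ArgumentError(f"{name} must lie in [0, 1], got {p}")
    return min(p_standard, p_deviant)


def combined_loo(
    std_X_raw, dev_X_raw, y, classifier_standard, classifier_deviant, patient_ids=None
) -> tuple[LooResult, LooResult, LooResult]:
    """LOO on both maps plus the min-combined decision.

    Returns (standard result, deviant result, combined result); the combined
    per-patient probability is min(p_standard, p_deviant) of the same fold.
    """
    res_std = leave_one_out(std_X_raw, y, classifier_standard, patient_ids)
    res_dev = leave_one_out(dev_X_raw, y, classifier_deviant, patient_ids)
    p_comb = [
        combine_decision(ps, pd_)
        for ps, pd_ in zip(res_std.per_patient["probability"],
                           res_dev.per_patient["probability"])
    ]
    report = res_std.per_patient[["patient_id", "label"]].copy()
    report["probability"] = p_comb
    report["predicted"] = np.where(np.array(p_comb) > 0.5, POSITIVE_LABEL, "bad")
    report["s_i"] = (report["predicted"] == report["label"]).astype(int)
    cm = ConfusionMatrix.from_predictions(report["label"], report["predicted"])
    res_comb = LooResult(per_patient=report, score=float(report["s_i"].mean()),
                         confusion=cm)
    return res_std, res_dev, res_comb


@dataclass(frozen=True)
class CohortTable2x2:
    """A 2×2 contingency table of cohort counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ArgumentError("table counts must be >= 0")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value of a 2×2 table.

    Two-sidedness follows the point-probability convention: the p-value sums
    the hypergeometric probabilities (margins fixed) of every table at least
    as extreme — point probability not exceeding the observed one.
    """
    if isinstance(table, CohortTable2x2):
        arr = np.array([[table.a, table.b], [table.c, table.d]])
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ArgumentError("table must be 2x2 with nonnegative counts")
    if arr.sum() == 0:
        raise ArgumentError("table must have at least one nonzero count")
    return float(fisher_exact(arr, alternative="two-sided")[1])
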