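"""Posterior-probability classifiers on a 2D feature map.

Three estimators share a scikit-learn interface (``fit``, ``predict``,
``predict_proba``, ``get_params``/``set_params``) plus a ``p_good`` helper
returning the posterior of the positive ("good neurological outcome") class:

- :class:`GaussianMapClassifier` — two-class Gaussian Bayes with per-class ML
  mean/covariance (1/N) and the empirical class prior;
- :class:`KNeighborsMapClassifier` — k-nearest-neighbour vote, optionally
  weighted by inverse Euclidean distance;
- :class:`RbfSvmMapClassifier` — soft-margin RBF SVM (γ=1, C=10 by default)
  with a slope-only sigmoid calibration anchored at p=0.5 on the boundary.

The hard-label rule is conservative toward specificity: a patient is called
"good" only when p(good) exceeds 0.5 strictly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ArgumentError, FitError
from .features import FeaturePoint

POSITIVE_LABEL = "good"


def _validate_two_class(y, positive_label):
    classes = np.unique(y)
    if len(classes) != 2:
        raise FitError(f"need exactly 2 classes, got {list(classes)}")
    if positive_label in classes:
        pos = positive_label
    else:
        pos = classes[1]
    return classes, pos


class _MapClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared two-class plumbing: label handling, predict, p_good."""

    def p_good(self, X) -> np.ndarray:
        """Posterior probability of the positive class at each query point."""
        check_is_fitted(self)
        proba = self.predict_proba(X)
        pos_idx = int(np.flatnonzero(self.classes_ == self.positive_class_)[0])
        return proba[:, pos_idx]

    def predict(self, X):
        p = self.p_good(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(p > 0.5, self.positive_class_, neg)

    def _check_query(self, X):
        X = check_array(np.asarray(X, dtype=float), ensure_2d=True,
                        ensure_all_finite=False)
        if not np.all(np.isfinite(X)):
            raise ArgumentError("query points must be finite")
        return X


class GaussianMapClassifier(_MapClassifierBase):
    """Two-class Gaussian Bayes posterior on the 2D map.

    p(good | x) = π N(x; μ₁, Σ₁) / [π N(x; μ₁, Σ₁) + (1−π) N(x; μ₂, Σ₂)]
    with per-class maximum-likelihood mean and covariance (1/N convention) and
    π the empirical fraction of good-labelled training points.  A covariance
    is regularized by ε·I (ε = ``reg_scale`` × mean diagonal) when its
    smallest eigenvalue falls below ε.
    """

    def __init__(self, reg_scale: float = 1e-6, positive_label: str = POSITIVE_LABEL):
        self.reg_scale = reg_scale
        self.positive_label = positive_label

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        self.classes_, self.positive_class_ = _validate_two_class(y, self.positive_label)
        self.means_, self.covariances_ = {}, {}
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise FitError(f"class {c!r} has fewer than 2 points")
            cov = np.cov(Xc, rowvar=False, bias=True)
            eps = self.reg_scale * np.mean(np.diag(cov))
            if eps <= 0 or np.linalg.eigvalsh(cov)[0] < eps:
                cov = cov + max(eps, np.finfo(float).tiny) * np.eye(X.shape[1])
            self.means_[c] = Xc.mean(axis=0)
            self.covariances_[c] = cov
        self.prior_ = float(np.mean(y == self.positive_class_))
        return self

    def _log_density(self, X, c):
        mu, cov = self.means_[c], self.covariances_[c]
        sign, logdet = np.linalg.slogdet(cov)
        diff = X - mu
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        d = X.shape[1]
        return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = self._check_query(X)
        log_post = np.empty((len(X), 2))
        for i, c in enumerate(self.classes_):
            prior = self.prior_ if c == self.positive_class_ else 1.0 - self.prior_
            log_post[:, i] = self._log_density(X, c) + np.log(max(prior, 1e-300))
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


class KNeighborsMapClassifier(_MapClassifierBase):
    """k-nearest-neighbour posterior, unweighted (k_r/K) or distance-weighted.

    Ties at the k-th distance are all included and the count renormalized, so
    the result is independent of training-point order.  In weighted mode an
    exact match (zero distance) short-circuits to the label fraction among
    the coincident training points.
    """

    def __init__(self, n_neighbors: int = 4, weighted: bool = False,
                 positive_label: str = POSITIVE_LABEL):
        self.n_neighbors = n_neighbors
        self.weighted = weighted
        self.positive_label = positive_label

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        if not 1 <= self.n_neighbors <= len(X):
            raise ArgumentError(
                f"n_neighbors must be in [1, {len(X)}], got {self.n_neighbors}"
            )
        self.classes_, self.positive_class_ = _validate_two_class(y, self.positive_label)
        self.X_, self.y_ = X, y
        return self

    def _p_good_single(self, x) -> float:
        d2 = np.sum((self.X_ - x) ** 2, axis=1)
        kth = np.partition(d2, self.n_neighbors - 1)[self.n_neighbors - 1]
        sel = d2 <= kth  # includes all points co-ranked with the k-th
        is_pos = self.y_[sel] == self.positive_class_
        if not self.weighted:
            return float(np.mean(is_pos))
        dsel = np.sqrt(d2[sel])
        if np.any(dsel == 0):
            exact = dsel == 0
            return float(np.mean(is_pos[exact]))
        w = 1.0 / dsel
        return float(np.sum(w[is_pos]) / np.sum(w))

    def predict_proba(self, X):
        check_is_fitted(self)
        X = self._check_query(X)
        p = np.array([self._p_good_single(x) for x in X])
        proba = np.empty((len(X), 2))
        for i, c in enumerate(self.classes_):
            proba[:, i] = p if c == self.positive_class_ else 1.0 - p
        return proba


class RbfSvmMapClassifier(_MapClassifierBase):
    """Soft-margin RBF SVM with a boundary-anchored sigmoid posterior.

    The decision surface comes from a standard dual solver; the posterior is
    p(good | x) = 1 / (1 + exp(−a·f(x))) with f the signed decision value
    (positive toward "good") and the single slope a > 0 fitted by maximum
    likelihood on the training decision values.  Having no intercept, the
    calibration pins p = 0.5 exactly on the decision boundary.
    """

    #: slope search interval; the upper bound caps the sharpness reached on
    #: perfectly separable training sets, where the ML slope diverges.
    _SLOPE_BOUNDS = (1e-3, 50.0)

    def __init__(self, gamma: float = 1.0, c_penalty: float = 10.0,
                 positive_label: str = POSITIVE_LABEL):
        self.gamma = gamma
        self.c_penalty = c_penalty
        self.positive_label = positive_label

    def fit(self, X, y):
        if self.gamma <= 0 or self.c_penalty <= 0:
            raise ArgumentError("gamma and c_penalty must be > 0")
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        self.classes_, self.positive_class_ = _validate_two_class(y, self.positive_label)
        self.svc_ = SVC(kernel="rbf", gamma=self.gamma, C=self.c_penalty)
        self.svc_.fit(X, y)
        # sklearn's decision_function is positive toward svc_.classes_[1]
        self._sign = 1.0 if self.svc_.classes_[1] == self.positive_class_ else -1.0
        scores = self._sign * self.svc_.decision_function(X)
        t = np.where(y == self.positive_class_, 1.0, -1.0)

        def negloglik(log_a):
            return float(np.sum(np.logaddexp(0.0, -np.exp(log_a) * t * scores)))

        res = minimize_scalar(
            negloglik, bounds=tuple(np.log(self._SLOPE_BOUNDS)), method="bounded"
        )
        self.sigmoid_slope_ = float(np.exp(res.x))
        self._train_X, self._train_y = X, y
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        return self._sign * self.svc_.decision_function(self._check_query(X))

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.sigmoid_slope_ * self.decision_function(X)))
        proba = np.empty((len(p), 2))
        for i, c in enumerate(self.classes_):
            proba[:, i] = p if c == self.positive_class_ else 1.0 - p
        return proba


@dataclass
class ProbabilityGrid:
    """Classifier posterior p(good | x) on a rectangle of the normalized map."""

    x_coords: np.ndarray
    y_coords: np.ndarray
    values: np.ndarray  # shape (len(y_coords), len(x_coords))

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.values, index=self.y_coords, columns=self.x_coords).to_csv(path)


DEFAULT_GRID_BOUNDS = (-3.0, 3.0, -3.0, 3.0)
DEFAULT_GRID_STEP = 0.05


def probability_grid(model, bounds=DEFAULT_GRID_BOUNDS, step: float = DEFAULT_GRID_STEP
                     ) -> ProbabilityGrid:
    """Evaluate a fitted classifier's p(good) on a regular grid."""
    if step <= 0:
        raise ArgumentError(f"step must be > 0, got {step}")
    x0, x1, y0, y1 = bounds
    xs = np.arange(x0, x1 + step / 2, step)
    ys = np.arange(y0, y1 + step / 2, step)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    values = model.p_good(pts).reshape(len(ys), len(xs))
    return ProbabilityGrid(x_coords=xs, y_coords=ys, values=values)


def update_with_patient(model, X, y, new_x, new_label):
    """Refit a classifier with one additional labelled patient.

    Refitting from scratch on the augmented set is exact for all three
    estimators (kNN stores the data; Gaussian moments and the SVM dual are
    recomputed), so no separate incremental path is kept.
    """
    if new_label is None or new_label == "unknown":
        raise ArgumentError("the new patient must carry a label")
    X_aug = np.vstack([np.asarray(X, dtype=float), np.asarray(new_x, dtype=float)])
    y_aug = np.append(np.asarray(y), new_label)
    return clone(model).fit(X_aug, y_aug)


# --- functional wrappers over the estimators ------------------------------

def points_to_xy(points: list[FeaturePoint]):
    """(X, y) arrays from a list of normalized map points."""
    X = np.array([[p.x, p.y] for p in points], dtype=float)
    y = np.array([p.label for p in points])
    return X, y


def fit_gaussian(points: list[FeaturePoint]) -> GaussianMapClassifier:
    return GaussianMapClassifier().fit(*points_to_xy(points))


def gaussian_posterior(model: GaussianMapClassifier, x) -> float:
    return float(model.p_good([x])[0])


def fit_knn(points: list[FeaturePoint], k: int = 4, weighted: bool = False
            ) -> KNeighborsMapClassifier:
    return KNeighborsMapClassifier(n_neighbors=k, weighted=weighted).fit(
        *points_to_xy(points)
    )


def knn_probability(model: KNeighborsMapClassifier, x) -> float:
    return float(model.p_good([x])[0])


weighted_knn_probability = knn_probability


def fit_svm(points: list[FeaturePoint], gamma: float = 1.0, c_penalty: float = 10.0
            ) -> RbfSvmMapClassifier:
    return RbfSvmMapClassifier(gamma=gamma, c_penalty=c_penalty).fit(*points_to_xy(points))


def svm_probability(model: RbfSvmMapClassifier, x) -> float:
    return float(model.p_good([x])[0])


# --- JSON round-tripping ---------------------------------------------------

def model_to_dict(model) -> dict:
    """Serializable description of a fitted classifier."""
    check_is_fitted(model)
    if isinstance(model, GaussianMapClassifier):
        return {
            "kind": "gaussian",
            "params": model.get_params(),
            "classes": model.classes_.tolist(),
            "means": {c: model.means_[c].tolist() for c in model.classes_},
            "covariances": {c: model.covariances_[c].tolist() for c in model.classes_},
            "prior": model.prior_,
        }
    if isinstance(model, KNeighborsMapClassifier):
        return {
            "kind": "knn",
            "params": model.get_params(),
            "X": model.X_.tolist(),
            "y": model.y_.tolist(),
        }
    if isinstance(model, RbfSvmMapClassifier):
        return {
            "kind": "svm",
            "params": model.get_params(),
            "X": model._train_X.tolist(),
            "y": model._train_y.tolist(),
        }
    raise ArgumentError(f"cannot serialize model of type {type(model).__name__}")


def model_from_dict(payload: dict):
    """Rebuild a classifier from :func:`model_to_dict` output.

    Gaussian models are restored from their moments; the data-driven models
    (kNN, SVM) are refitted from the stored training points, which is exact
    because both fits are deterministic.
    """
    kind = payload["kind"]
    params = payload.get("params", {})
    if kind == "gaussian":
        model = GaussianMapClassifier(**params)
        model.classes_ = np.array(payload["classes"])
        model.positive_class_ = (
            model.positive_label
            if model.positive_label in model.classes_
            else model.classes_[1]
        )
        model.means_ = {c: np.array(payload["means"][c]) for c in model.classes_}
        model.covariances_ = {
            c: np.array(payload["covariances"][c]) for c in model.classes_
        }
        model.prior_ = float(payload["prior"])
        return model
    if kind == "knn":
        return KNeighborsMapClassifier(**params).fit(payload["X"], payload["y"])
    if kind == "svm":
        return RbfSvmMapClassifier(**params).fit(payload["X"], payload["y"])
    raise ArgumentError(f"unknown model kind {kind!r}")


def save_model(model, path):
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
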