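import numpy as np
import pytest

from aepmap import (
    ArgumentError,
    FitError,
    GaussianMapClassifier,
    KNeighborsMapClassifier,
    RbfSvmMapClassifier,
    model_from_dict,
    model_to_dict,
    probability_grid,
    update_with_patient,
)


def two_clusters(n_good=6, n_bad=23, sep=4.0, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    Xg = rng.normal([sep / 2, 0.0], spread, size=(n_good, 2))
    Xb = rng.normal([-sep / 2, 0.0], spread, size=(n_bad, 2))
    X = np.vstack([Xg, Xb])
    y = np.array(["good"] * n_good + ["bad"] * n_bad)
    return X, y


def gaussian_with(mu1, mu2, cov1, cov2, prior):
    """Assemble a Gaussian model directly from its moments."""
    m = GaussianMapClassifier()
    m.classes_ = np.array(["bad", "good"])
    m.positive_class_ = "good"
    m.means_ = {"good": np.asarray(mu1, float), "bad": np.asarray(mu2, float)}
    m.covariances_ = {"good": np.asarray(cov1, float), "bad": np.asarray(cov2, float)}
    m.prior_ = prior
    return m


class TestGaussianClassifier:
    def test_recovers_tight_cluster_means(self):
        rng = np.random.default_rng(1)
        Xg = np.array([1.0, 2.0]) + rng.normal(0, 1e-3, size=(10, 2))
        Xb = np.array([-3.0, 0.5]) + rng.normal(0, 1e-3, size=(10, 2))
        model = GaussianMapClassifier().fit(
            np.vstack([Xg, Xb]), ["good"] * 10 + ["bad"] * 10
        )
        np.testing.assert_allclose(model.means_["good"], [1.0, 2.0], atol=1e-3)
        np.testing.assert_allclose(model.means_["bad"], [-3.0, 0.5], atol=1e-3)

    def test_prior_is_class_fraction(self):
        X, y = two_clusters(n_good=6, n_bad=23)
        model = GaussianMapClassifier().fit(X, y)
        assert model.prior_ == pytest.approx(6 / 29)

    def test_hand_posterior(self):
        """Equal priors, unit covariances, means (0,0) and (2,0): the
        posterior at the good mean is 1/(1+e^-2)."""
        m = gaussian_with([0, 0], [2, 0], np.eye(2), np.eye(2), 0.5)
        assert m.p_good([[0.0, 0.0]])[0] == pytest.approx(1 / (1 + np.exp(-2)))

    def test_equidistant_point_with_equal_priors(self):
        m = gaussian_with([1, 0], [-1, 0], np.eye(2), np.eye(2), 0.5)
        assert m.p_good([[0.0, 5.0]])[0] == pytest.approx(0.5)

    def test_posterior_monotone_in_prior(self):
        x = [[0.3, -0.2]]
        probs = [
            gaussian_with([1, 0], [-1, 0], np.eye(2), np.eye(2), pi).p_good(x)[0]
            for pi in np.linspace(0.05, 0.999, 30)
        ]
        assert np.all(np.diff(probs) > 0)
        assert probs[-1] > 0.99

    def test_moment_recovery_from_samples(self):
        """ML estimates land within 3 standard errors of the sampling truth."""
        rng = np.random.default_rng(5)
        mu, cov, n = np.array([1.0, -2.0]), np.array([[2.0, 0.6], [0.6, 1.0]]), 500
        Xg = rng.multivariate_normal(mu, cov, size=n)
        Xb = rng.multivariate_normal(-mu, cov, size=n)
        model = GaussianMapClassifier().fit(
            np.vstack([Xg, Xb]), ["good"] * n + ["bad"] * n
        )
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(model.means_["good"] - mu) < 3 * se_mean)
        # covariance entries: SE ~ sqrt((c_ii c_jj + c_ij^2)/n)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((cov[i, i] * cov[j, j] + cov[i, j] ** 2) / n)
                assert abs(model.covariances_["good"][i, j] - cov[i, j]) < 3 * se

    def test_single_point_class_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.1, 0.9]])
        with pytest.raises(FitError):
            GaussianMapClassifier().fit(X, ["good", "bad", "bad"])

    def test_nonfinite_query_rejected(self):
        X, y = two_clusters()
        model = GaussianMapClassifier().fit(X, y)
        with pytest.raises(ArgumentError):
            model.p_good([[np.nan, 0.0]])

    def test_equal_covariances_give_linear_boundary(self):
        """With shared covariance the quadratic terms cancel: the p=0.5 set
        matches the closed-form linear discriminant."""
        mu1, mu2 = np.array([1.5, 0.5]), np.array([-1.0, -0.5])
        cov = np.array([[1.2, 0.3], [0.3, 0.8]])
        m = gaussian_with(mu1, mu2, cov, cov, 0.5)
        w = np.linalg.solve(cov, mu1 - mu2)
        b = -0.5 * (mu1 + mu2) @ w
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 2, size=(50, 2))
        # project points onto the LDA boundary: w.x + b = 0
        pts_on = pts - ((pts @ w + b) / (w @ w))[:, None] * w
        np.testing.assert_allclose(m.p_good(pts_on), 0.5, atol=1e-9)


class TestKnnClassifier:
    def test_all_good_neighbors(self):
        X = np.array([[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [5, 5], [6, 6]])
        y = np.array(["good"] * 4 + ["bad"] * 2)
        m = KNeighborsMapClassifier(n_neighbors=4).fit(X, y)
        assert m.p_good([[0.05, 0.05]])[0] == 1.0

    def test_three_of_four(self):
        X = np.array([[1, 0], [0, 1], [-1, 0], [0, -1], [9, 9]])
        y = np.array(["good", "good", "good", "bad", "bad"])
        m = KNeighborsMapClassifier(n_neighbors=4).fit(X, y)
        assert m.p_good([[0.0, 0.0]])[0] == 0.75

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ArgumentError):
            KNeighborsMapClassifier(n_neighbors=5).fit(
                np.zeros((4, 2)), ["good", "good", "bad", "bad"]
            )

    def test_matches_brute_force_oracle(self):
        """Agreement with an independent O(n^2) neighbour search on 500
        random queries (generic positions, no distance ties)."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = np.where(rng.random(60) < 0.3, "good", "bad")
        k = 7
        m = KNeighborsMapClassifier(n_neighbors=k).fit(X, y)
        for _ in range(500):
            q = rng.normal(size=2)
            d = np.array([np.hypot(*(xi - q)) for xi in X])
            nearest = np.argsort(d)[:k]
            expected = np.mean(y[nearest] == "good")
            assert m.p_good([q])[0] == pytest.approx(expected)

    def test_distance_ties_include_corank_and_renormalize(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])  # all at distance 1
        y = np.array(["good", "good", "good", "bad"])
        m = KNeighborsMapClassifier(n_neighbors=2).fit(X, y)
        # the 2-nearest request hits a 4-way tie: all points enter the vote
        assert m.p_good([[0.0, 0.0]])[0] == 0.75

    def test_weighted_equidistant_reduces_to_unweighted(self):
        X = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]])
        y = np.array(["good", "good", "bad", "bad"])
        m = KNeighborsMapClassifier(n_neighbors=4, weighted=True).fit(X, y)
        assert m.p_good([[0.0, 0.0]])[0] == 0.5

    def test_weighted_hand_value(self):
        """Two neighbours at d=1 (good) and d=3 (bad): p = (1/1)/(1/1+1/3)."""
        X = np.array([[1.0, 0.0], [-3.0, 0.0]])
        y = np.array(["good", "bad"])
        m = KNeighborsMapClassifier(n_neighbors=2, weighted=True).fit(X, y)
        assert m.p_good([[0.0, 0.0]])[0] == pytest.approx(0.75)

    def test_weighted_exact_match_rule(self):
        X = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        y = np.array(["good", "bad", "bad"])
        m = KNeighborsMapClassifier(n_neighbors=2, weighted=True).fit(X, y)
        assert m.p_good([[1.0, 1.0]])[0] == 1.0


class TestSvmClassifier:
    def test_separable_training_accuracy(self):
        X, y = two_clusters(sep=6.0, spread=0.5, seed=3)
        m = RbfSvmMapClassifier().fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_xor_arrangement_solved_by_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["good", "good", "bad", "bad"])
        m = RbfSvmMapClassifier(gamma=1.0, c_penalty=10.0).fit(X, y)
        assert list(m.predict(X)) == list(y)

    def test_soft_margin_tolerates_interior_label_flip(self):
        """The cluster is dense relative to the gamma=1 kernel width, so the
        solver cannot carve an island around one flipped label: with C=10 it
        pays the slack and misclassifies the flipped point instead."""
        X, y = two_clusters(n_good=25, n_bad=25, sep=4.0, spread=0.15, seed=4)
        # flip the deepest good-side point to "bad"
        flip = np.argmax(X[:, 0])
        y_flipped = y.copy()
        y_flipped[flip] = "bad"
        m = RbfSvmMapClassifier(c_penalty=10.0).fit(X, y_flipped)
        pred = m.predict(X)
        assert pred[flip] == "good"  # the outlier is sacrificed
        others = np.ones(len(X), dtype=bool)
        others[flip] = False
        assert np.mean(pred[others] == y[others]) == 1.0

    def test_confusion_stable_over_gamma_c_plane(self):
        """On a separable cohort the training confusion is identical for all
        (gamma, C) in [0.5, 2.5] x [3, 30]."""
        X, y = two_clusters(sep=5.0, spread=0.6, seed=6)
        references = None
        for gamma in (0.5, 1.5, 2.5):
            for c in (3.0, 10.0, 30.0):
                pred = RbfSvmMapClassifier(gamma=gamma, c_penalty=c).fit(X, y).predict(X)
                if references is None:
                    references = pred
                np.testing.assert_array_equal(pred, references)

    def test_half_probability_on_decision_boundary(self):
        X, y = two_clusters(sep=4.0, spread=0.8, seed=7)
        m = RbfSvmMapClassifier().fit(X, y)
        # bisect the decision value along the segment between class centroids
        a = X[y == "bad"].mean(axis=0)
        b = X[y == "good"].mean(axis=0)
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if m.decision_function([a + mid * (b - a)])[0] < 0:
                lo = mid
            else:
                hi = mid
        boundary_point = a + ((lo + hi) / 2) * (b - a)
        assert m.p_good([boundary_point])[0] == pytest.approx(0.5, abs=1e-6)

    def test_monotone_along_ray_through_boundary(self):
        X, y = two_clusters(sep=4.0, spread=0.8, seed=9)
        m = RbfSvmMapClassifier().fit(X, y)
        a = X[y == "bad"].mean(axis=0)
        b = X[y == "good"].mean(axis=0)
        ts = np.linspace(0, 1, 50)
        p = m.p_good(a[None, :] + ts[:, None] * (b - a)[None, :])
        assert np.all(np.diff(p) > -1e-12)
        assert p[0] < 0.5 < p[-1]

    def test_deep_inside_good_cluster(self):
        X, y = two_clusters(sep=6.0, spread=0.5, seed=10)
        m = RbfSvmMapClassifier().fit(X, y)
        assert m.p_good([X[y == "good"].mean(axis=0)])[0] > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            RbfSvmMapClassifier().fit(np.zeros((3, 2)), ["bad", "bad", "bad"])


class TestProbabilityGrid:
    def test_values_match_direct_calls(self):
        X, y = two_clusters(seed=11)
        knn = KNeighborsMapClassifier(4).fit(X, y)
        grid = probability_grid(knn, bounds=(-1, 1, -1, 1), step=0.5)
        assert grid.values.shape == (5, 5)
        for i, yv in enumerate(grid.y_coords):
            for j, xv in enumerate(grid.x_coords):
                # kNN evaluates one query at a time: bitwise identical
                assert grid.values[i, j] == knn.p_good([[xv, yv]])[0]
        gauss = GaussianMapClassifier().fit(X, y)
        grid_g = probability_grid(gauss, bounds=(-1, 1, -1, 1), step=0.5)
        direct = np.array(
            [[gauss.p_good([[xv, yv]])[0] for xv in grid_g.x_coords]
             for yv in grid_g.y_coords]
        )
        # batched einsum may differ from single-point calls by an ulp
        np.testing.assert_allclose(grid_g.values, direct, atol=1e-12)

    def test_default_grid_shape(self):
        X, y = two_clusters(seed=12)
        grid = probability_grid(KNeighborsMapClassifier(4).fit(X, y))
        assert grid.values.shape == (121, 121)
        assert np.all((grid.values >= 0) & (grid.values <= 1))

    def test_symmetric_gaussian_grid_antisymmetry(self):
        m = gaussian_with([1, 0], [-1, 0], np.eye(2), np.eye(2), 0.5)
        grid = probability_grid(m, bounds=(-2, 2, -2, 2), step=0.25)
        np.testing.assert_allclose(
            grid.values + grid.values[:, ::-1], 1.0, atol=1e-9
        )

    def test_bad_step_rejected(self):
        X, y = two_clusters(seed=13)
        with pytest.raises(ArgumentError):
            probability_grid(GaussianMapClassifier().fit(X, y), step=0.0)

    def test_three_classifiers_agree_at_cluster_centroids(self):
        """On well-separated cohorts every classifier family reproduces the
        same partition where the data determine it: all three label both
        class centroids identically, for every seed tried.  (Away from the
        data support the families extrapolate differently by construction —
        the kNN bisector, the RBF far field, the quadratic Gaussian boundary
        — so grid-wide agreement is not a property of these estimators.)"""
        for seed in range(10):
            X, y = two_clusters(sep=4.0, spread=0.6, seed=seed)
            centroids = np.vstack(
                [X[y == "good"].mean(axis=0), X[y == "bad"].mean(axis=0)]
            )
            for clf in (GaussianMapClassifier(), KNeighborsMapClassifier(4),
                        RbfSvmMapClassifier()):
                pred = clf.fit(X, y).predict(centroids)
                assert list(pred) == ["good", "bad"]


class TestUpdateWithPatient:
    def test_gaussian_mean_moves_at_most_one_over_n_plus_one(self):
        X, y = two_clusters(n_good=10, n_bad=10, seed=15)
        m = GaussianMapClassifier().fit(X, y)
        dup = X[0]  # an existing good point
        m2 = update_with_patient(m, X, y, dup, "good")
        shift = np.linalg.norm(m2.means_["good"] - m.means_["good"])
        radius = np.linalg.norm(dup - m.means_["good"])
        assert shift <= radius / 11 + 1e-12

    def test_knn_probability_moves_toward_new_label(self):
        X, y = two_clusters(seed=16)
        m = KNeighborsMapClassifier(n_neighbors=4).fit(X, y)
        q = np.array([10.0, 10.0])
        before = m.p_good([q])[0]
        m2 = update_with_patient(m, X, y, q, "good")
        assert m2.p_good([q])[0] >= before

    def test_incremental_equals_refit(self):
        X, y = two_clusters(seed=17)
        new_x, new_label = np.array([0.5, 0.5]), "good"
        X_aug = np.vstack([X, new_x])
        y_aug = np.append(y, new_label)
        for clf in (GaussianMapClassifier(), KNeighborsMapClassifier(4),
                    RbfSvmMapClassifier()):
            updated = update_with_patient(clf.fit(X, y), X, y, new_x, new_label)
            scratch = type(clf)(**clf.get_params()).fit(X_aug, y_aug)
            q = np.array([[0.2, -0.3], [1.5, 0.0]])
            np.testing.assert_allclose(updated.p_good(q), scratch.p_good(q),
                                       atol=1e-9)

    def test_unlabeled_point_rejected(self):
        X, y = two_clusters(seed=18)
        m = KNeighborsMapClassifier(4).fit(X, y)
        with pytest.raises(ArgumentError):
            update_with_patient(m, X, y, [0, 0], "unknown")


class TestModelSerialization:
    @pytest.mark.parametrize(
        "clf",
        [GaussianMapClassifier(), KNeighborsMapClassifier(4, weighted=True),
         RbfSvmMapClassifier()],
        ids=["gaussian", "weighted_knn", "svm"],
    )
    def test_json_round_trip_preserves_posteriors(self, clf, tmp_path):
        import json

        X, y = two_clusters(seed=19)
        model = clf.fit(X, y)
        payload = json.loads(json.dumps(model_to_dict(model)))
        restored = model_from_dict(payload)
        q = np.array([[0.0, 0.0], [2.0, 1.0], [-3.0, 0.5]])
        np.testing.assert_allclose(restored.p_good(q), model.p_good(q), atol=1e-9)


class TestPosteriorInvariants:
    @pytest.mark.parametrize(
        "clf",
        [GaussianMapClassifier(), KNeighborsMapClassifier(4),
         KNeighborsMapClassifier(4, weighted=True), RbfSvmMapClassifier()],
        ids=["gaussian", "knn", "weighted_knn", "svm"],
    )
    def test_probabilities_in_unit_interval_and_sum_to_one(self, clf):
        X, y = two_clusters(seed=20)
        model = clf.fit(X, y)
        rng = np.random.default_rng(21)
        q = rng.normal(0, 3, size=(100, 2))
        proba = model.predict_proba(q)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
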