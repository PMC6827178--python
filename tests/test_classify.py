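import numpy as np
import pytest

from pathrobust.classify import (CVScheme, complexity_sweep, cross_validate,
                                 cross_validate_multi, cv_predictions,
                                 fit_classifier, fit_knn, fit_plsda, fit_svm,
                                 plsda_response, predict_class,
                                 select_complexity)
from pathrobust.data import PathwayCollection
from pathrobust.degradation import DegradationConfig, degrade
from pathrobust.scoring import score_matrix

from conftest import make_expression


def separable_data(n=12, seed=0):
    r = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2), dtype=object)
    X = r.standard_normal((n, 4))
    X[:, 0] = np.where(y == "a", -5.0, 5.0) + 0.1 * r.standard_normal(n)
    return X, y


class TestPlsda:
    def test_separable_training_accuracy(self):
        X, y = separable_data()
        model = fit_plsda(X, y, 1)
        assert np.mean(predict_class(model, X) == y) == 1.0

    def test_row_permutation_equivariance(self):
        X, y = separable_data(seed=3)
        perm = np.random.default_rng(1).permutation(len(y))
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X[perm], y[perm], 2)
        assert np.allclose(m1.B, m2.B, atol=1e-10)

    def test_full_complexity_equals_ols_on_dummies(self):
        # with n_comp = min(n-1, p) PLS2 spans the OLS solution
        r = np.random.default_rng(5)
        X = r.standard_normal((20, 6))
        y = np.array(["a", "b"] * 10, dtype=object)
        model = fit_plsda(X, y, 6)
        pred = plsda_response(model, X)
        Y = np.column_stack([(y == "a"), (y == "b")]).astype(float)
        Xc = X - X.mean(axis=0)
        B_ols, *_ = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)
        pred_ols = Xc @ B_ols + Y.mean(axis=0)
        assert np.allclose(pred, pred_ols, atol=1e-8)

    def test_truncated_response_equals_refit(self):
        r = np.random.default_rng(9)
        X = r.standard_normal((30, 10))
        y = np.array(["a", "b", "c"] * 10, dtype=object)
        big = fit_plsda(X, y, 5)
        for k in (1, 2, 3, 4):
            small = fit_plsda(X, y, k)
            assert np.allclose(plsda_response(big, X, n_comp=k),
                               plsda_response(small, X), atol=1e-10)

    def test_errors(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="min\\(n-1, p\\)"):
            fit_plsda(X, y, 100)
        with pytest.raises(ValueError, match="two classes"):
            fit_plsda(X, np.array(["a"] * len(y)), 1)

    def test_one_component_two_class_decision_monotone(self):
        # ranking by the predicted "a" response equals ranking by the
        # first latent score
        X, y = separable_data(seed=7)
        model = fit_plsda(X, y, 1)
        resp = plsda_response(model, X)[:, 0]
        t = (X - model.x_mean) @ model.x_rotations[:, 0]
        assert (np.argsort(resp) == np.argsort(t)).all() or \
               (np.argsort(resp) == np.argsort(-t)).all()


class TestPredict:
    def test_knn_tie_broken_by_mean_distance(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = fit_knn(X, y, 2)
        # query at 5.6: nearest 2 are one "a" (4.6) and one "b" (4.4) -> "b"
        assert predict_class(model, np.array([[5.6]]))[0] == "b"
        assert predict_class(model, np.array([[5.4]]))[0] == "a"

    def test_knn_k1_training_accuracy(self):
        X = np.random.default_rng(0).standard_normal((15, 3))
        y = np.array(["a", "b", "c"] * 5, dtype=object)
        model = fit_knn(X, y, 1)
        assert np.mean(predict_class(model, X) == y) == 1.0

    def test_plsda_argmax_matches_brute_force(self):
        r = np.random.default_rng(2)
        X = r.standard_normal((30, 8))
        y = np.array(["a", "b", "c"] * 10, dtype=object)
        model = fit_plsda(X, y, 3)
        resp = plsda_response(model, X)
        expected = np.array([model.classes[int(np.argmax(row))] for row in resp])
        assert np.array_equal(predict_class(model, X), expected)

    def test_svm_separable(self):
        X, y = separable_data()
        model = fit_svm(X, y, 1.0)
        assert np.mean(predict_class(model, X) == y) == 1.0

    def test_column_mismatch_rejected(self):
        X, y = separable_data()
        model = fit_plsda(X, y, 1)
        with pytest.raises(ValueError, match="predictor columns"):
            predict_class(model, X[:, :2])


class TestCrossValidate:
    def test_separable_is_perfect(self):
        X, y = separable_data(n=16)
        for kind, cx in (("plsda", 1), ("knn", 3), ("svm", 1.0)):
            acc = cross_validate(X, y, None, kind, cx,
                                 CVScheme("stratified_kfold", 2, seed=0))
            assert acc == 1.0

    def test_chance_level_on_random_labels(self):
        # accuracy over reruns hovers at 1/2 for label-independent features
        accs = []
        for i in range(50):
            r = np.random.default_rng(i)
            X = r.standard_normal((40, 5))
            y = np.array(["a", "b"] * 20, dtype=object)
            accs.append(cross_validate(X, y, None, "plsda", 2,
                                       CVScheme("stratified_kfold", 2, seed=i)))
        assert abs(np.mean(accs) - 0.5) < 4 * np.sqrt(0.25 / (50 * 40))

    def test_logo_folds_match_hand_enumeration(self):
        X = np.random.default_rng(1).standard_normal((9, 3))
        y = np.array(["a", "a", "a", "b", "b", "b", "a", "b", "a"], dtype=object)
        groups = np.array(["g1", "g1", "g1", "g2", "g2", "g2", "g3", "g2", "g3"],
                          dtype=object)
        scheme = CVScheme("leave_one_group_out")
        folds = list(scheme.folds(y, groups))
        assert len(folds) == 3
        expected_tests = [[0, 1, 2], [3, 4, 5, 7], [6, 8]]  # g1, g2, g3 sorted
        for (train, test), exp in zip(folds, expected_tests):
            assert sorted(test) == exp
            assert sorted(np.concatenate([train, test])) == list(range(9))

    def test_every_sample_predicted_once(self):
        X, y = separable_data(n=14, seed=4)
        pred = cv_predictions(X, y, None, "knn", 1,
                              CVScheme("stratified_kfold", 2, seed=1))
        assert pred.shape == y.shape  # one prediction per sample

    def test_fold_missing_class_errors(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        y = np.array(["a", "a", "a", "a", "b", "b"], dtype=object)
        groups = np.array(["g1", "g1", "g2", "g2", "g3", "g3"], dtype=object)
        with pytest.raises(ValueError, match="lacks class"):
            cross_validate(X, y, groups, "plsda", 1, CVScheme("leave_one_group_out"))

    def test_logo_without_groups_errors(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="group"):
            cross_validate(X, y, None, "plsda", 1, CVScheme("leave_one_group_out"))

    def test_multi_candidate_equals_individual_runs(self):
        expr = make_expression(n=24, m=12, n_classes=3, seed=6)
        scheme = CVScheme("stratified_kfold", 2, seed=3)
        multi = cross_validate_multi(expr.values, expr.class_labels, None,
                                     "plsda", [1, 2, 4], scheme)
        for c in (1, 2, 4):
            single = cross_validate(expr.values, expr.class_labels, None,
                                    "plsda", c, scheme)
            assert multi[c] == single


class TestSelectComplexity:
    @pytest.fixture
    def setting(self, small_synthetic):
        from pathrobust.data import restrict_to_universe

        expr, coll = small_synthetic
        expr, coll = restrict_to_universe(expr, coll)
        config = DegradationConfig(levels=(0.0, 0.5, 1.0), n_repeats=2, seed=5)
        scheme = CVScheme("leave_one_group_out")
        return expr, coll, config, scheme

    def test_single_candidate_returned(self, setting):
        expr, coll, config, scheme = setting
        assert select_complexity(expr, coll, [3], config, scheme) == 3

    def test_matches_brute_force_sum_of_medians(self, setting):
        expr, coll, config, scheme = setting
        candidates = [1, 2, 4]
        sweep = complexity_sweep(expr, coll, candidates, config, scheme)
        # independent recomputation: degrade/score/evaluate per candidate
        for cand in candidates:
            table = np.zeros((len(config.levels), config.n_repeats))
            for li, level in enumerate(config.levels):
                for rep in range(config.n_repeats):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([config.seed, li, rep]))
                    degraded = degrade(expr, level, config.method, rng)
                    scores = score_matrix(degraded, coll, "pca")
                    table[li, rep] = cross_validate(
                        scores.scores, expr.class_labels, expr.group_labels,
                        "plsda", cand, scheme)
            assert np.allclose(sweep["accuracies"][cand], table)
            assert np.isclose(sweep["sums"][cand],
                              np.median(table, axis=1).sum())
        best = max(candidates,
                   key=lambda c: (sweep["sums"][c], -c))
        assert sweep["best"] == best

    def test_empty_candidates_error(self, setting):
        expr, coll, config, scheme = setting
        with pytest.raises(ValueError, match="empty candidate"):
            select_complexity(expr, coll, [], config, scheme)


def test_fit_classifier_dispatch():
    X, y = separable_data()
    for kind in ("plsda", "knn"):
        assert fit_classifier(kind, X, y, 1).kind == kind
    with pytest.raises(ValueError, match="unknown classifier"):
        fit_classifier("forest", X, y, 1)
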