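"""Unit, oracle and property tests for the PLS core."""

import numpy as np
import pytest

from cytopls.pls import (
    PLSError,
    _null_pvalue,
    autoscale,
    encode_labels,
    fit_plsda,
    fit_plsr,
    loo_cv,
    nipals_pls,
    orthogonalize,
    permutation_test,
    predict,
    predict_labels,
    select_num_lvs,
    vip,
)
from oracles import svd_pls_coefficients


def fit(X, y, A):
    """Autoscale + center + NIPALS, returning (model, scaling)."""
    Z, scaling = autoscale(X)
    model = nipals_pls(Z, y - y.mean(), A, y_mean=float(np.mean(y)))
    return model, scaling


class TestAutoscale:
    def test_small_column(self):
        Z, s = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1, 0, 1])

    def test_idempotent_and_moments(self, rng):
        X = rng.normal(3, 7, (6, 4))
        Z, _ = autoscale(X)
        assert np.all(np.abs(Z.mean(0)) < 1e-12)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1.0, atol=1e-12)
        Z2, _ = autoscale(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-12)

    def test_zero_variance_names_predictor(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(PLSError, match="flat"):
            autoscale(X, ["flat", "ok"])


class TestNipals:
    def test_single_predictor_exact_fit(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2 * x[:, 0]
        model, scaling = fit(x, y, 1)
        yhat = predict(model, scaling, x)
        np.testing.assert_allclose(yhat, y, atol=1e-10)

    def test_orthogonal_design_weight_direction(self):
        # y correlates only with the first of two orthogonal predictors
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0])
        y = 3 * x1
        model, _ = fit(np.column_stack([x1, x2]), y, 1)
        w = model.W[:, 0]
        assert abs(abs(w[0]) - 1) < 1e-8 and abs(w[1]) < 1e-8

    def test_matches_svd_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 13))
            p = int(rng.integers(2, 9))
            A = int(rng.integers(1, min(n - 1, p) + 1))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Z, _ = autoscale(X)
            yc = y - y.mean()
            model = nipals_pls(Z, yc, A)
            b_oracle = svd_pls_coefficients(Z, yc, A)
            np.testing.assert_allclose(model.b, b_oracle, atol=1e-6)

    def test_matches_sklearn_coefficients(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(10):
            X = rng.normal(size=(10, 6))
            y = rng.normal(size=10)
            Z, _ = autoscale(X)
            yc = y - y.mean()
            model = nipals_pls(Z, yc, 3)
            ref = sklearn.PLSRegression(n_components=3, scale=False).fit(Z, yc)
            np.testing.assert_allclose(model.b, np.ravel(ref.coef_), atol=1e-8)

    def test_score_orthogonality_and_reconstruction(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        Z, _ = autoscale(X)
        A = np.linalg.matrix_rank(Z)
        model = nipals_pls(Z, y - y.mean(), A)
        T = model.T
        G = T.T @ T
        offdiag = G - np.diag(np.diag(G))
        norms = np.linalg.norm(T, axis=0)
        assert np.max(np.abs(offdiag) / np.outer(norms, norms)) < 1e-8
        recon = T @ model.P.T
        assert np.linalg.norm(Z - recon) / np.linalg.norm(Z) < 1e-6

    def test_training_predictions_equal_score_route(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model, scaling = fit(X, y, 3)
        yhat_b = predict(model, scaling, X)
        yhat_t = model.T @ model.q + model.y_mean
        np.testing.assert_allclose(yhat_b, yhat_t, rtol=1e-8, atol=1e-10)

    def test_invalid_component_count(self):
        Z = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(PLSError):
            nipals_pls(Z, np.arange(5.0) - 2, 5)


class TestOrthogonalize:
    def test_one_lv_is_identity(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model, _ = fit(X, y, 1)
        rot = orthogonalize(model)
        assert rot.orthogonalized
        np.testing.assert_array_equal(rot.T, model.T)

    def test_predictions_preserved(self, rng):
        for _ in range(10):
            X = rng.normal(size=(10, 6))
            y = rng.normal(size=10)
            model, scaling = fit(X, y, 3)
            rot = orthogonalize(model)
            yhat_before = model.T @ model.q
            yhat_after = rot.T @ rot.q
            np.testing.assert_allclose(yhat_after, yhat_before, atol=1e-10)
            # coefficient route unchanged
            np.testing.assert_allclose(rot.b, model.b)

    def test_lv1_covariance_is_maximal_over_rotations(self, rng):
        # brute force over a fine grid of 2-D rotation angles of the
        # orthonormalized score space
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model, _ = fit(X, y, 2)
        rot = orthogonalize(model)
        yc = y - y.mean()
        U = model.T / np.linalg.norm(model.T, axis=0)
        best = max(
            abs(np.cos(a) * (U[:, 0] @ yc) + np.sin(a) * (U[:, 1] @ yc))
            for a in np.linspace(0, 2 * np.pi, 5000)
        )
        lv1 = rot.T[:, 0] / np.linalg.norm(rot.T[:, 0])
        assert abs(lv1 @ yc) >= best - 1e-4
        # per-LV covariances before rotation never exceed the rotated LV1
        for a in range(2):
            ua = model.T[:, a] / np.linalg.norm(model.T[:, a])
            assert abs(ua @ yc) <= abs(lv1 @ yc) + 1e-10

    def test_higher_lvs_uncorrelated_with_fitted_response(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model, _ = fit(X, y, 3)
        rot = orthogonalize(model)
        yhat = rot.T @ rot.q
        for a in range(1, rot.A):
            assert abs(rot.T[:, a] @ yhat) < 1e-10

    def test_scores_remain_orthogonal(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model, _ = fit(X, y, 3)
        rot = orthogonalize(model)
        G = rot.T.T @ rot.T
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-10)


class TestPredict:
    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model, scaling = fit(X, y, 2)
        yhat = predict(model, scaling, X.mean(axis=0))
        np.testing.assert_allclose(yhat, [y.mean()], atol=1e-10)

    def test_column_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        model, scaling = fit(X, rng.normal(size=8), 2)
        with pytest.raises(PLSError):
            predict(model, scaling, np.zeros((2, 5)))

    def test_separated_groups_classified(self, rng):
        X = rng.normal(size=(12, 4))
        X[6:] += 6.0
        labels = np.array(["a"] * 6 + ["b"] * 6)
        y, classes = encode_labels(labels)
        model, scaling = fit(X, y, 1)
        X_new = rng.normal(size=(4, 4))
        X_new[2:] += 6.0
        got = predict_labels(model, scaling, X_new, classes)
        assert got.tolist() == ["a", "a", "b", "b"]


class TestCV:
    def test_separated_groups_zero_error(self, rng):
        X = rng.normal(size=(10, 6))
        X[5:] += 5.0
        y, _ = encode_labels(["a"] * 5 + ["b"] * 5)
        assert loo_cv(X, y, 1, classification=True) == 0.0

    def test_null_error_near_half(self):
        errs = []
        for s in range(100):
            r = np.random.default_rng(s)
            X = r.normal(size=(10, 5))
            y, _ = encode_labels(["a", "b"] * 5)
            errs.append(loo_cv(X, y, 1, classification=True))
        assert 0.35 < np.mean(errs) < 0.65

    def test_minimal_n_runs(self, rng):
        X = rng.normal(size=(4, 3))
        y, _ = encode_labels(["a", "a", "b", "b"])
        err = loo_cv(X, y, 1, classification=True)
        assert err in {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_scaling_refit_inside_folds(self, rng):
        # an extreme held-out sample must not leak into the fold's scaling:
        # regression MSE computed by hand for one fold
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        err = loo_cv(X, y, 1, classification=False)
        hand = 0.0
        for i in range(6):
            m = np.arange(6) != i
            Z, scaling = autoscale(X[m])
            mdl = nipals_pls(Z, y[m] - y[m].mean(), 1, y_mean=float(y[m].mean()))
            hand += (predict(mdl, scaling, X[i])[0] - y[i]) ** 2
        assert err == pytest.approx(hand / 6)

    def test_rank_one_signal_selects_one_lv(self):
        # one strong latent factor plus isotropic noise: a single component
        # already reaches the noise floor, and extra LVs only fit noise
        r = np.random.default_rng(1)
        t = r.normal(size=12)
        X = np.outer(t, r.normal(size=6)) + 0.05 * r.normal(size=(12, 6))
        y = t + 0.3 * r.normal(size=12)
        cv = select_num_lvs(X, y, 4, classification=False)
        assert cv.A_star == 1
        assert cv.errors_by_A[0] < 2 * 0.3**2  # near the planted y-noise floor

    def test_tie_break_toward_fewer_lvs(self, rng):
        X = rng.normal(size=(10, 5))
        X[5:] += 8.0  # separation so extreme every A gives error 0
        y, _ = encode_labels(["a"] * 5 + ["b"] * 5)
        cv = select_num_lvs(X, y, 3, classification=True)
        assert np.all(cv.errors_by_A == cv.errors_by_A[0])
        assert cv.A_star == 1


class TestPermutation:
    def test_observed_at_null_mean_gives_half(self):
        null = np.array([0.4, 0.5, 0.6] * 10)
        p, _ = _null_pvalue(float(np.mean(null)), null, classification=True)
        assert p == pytest.approx(0.5)

    def test_degenerate_null_branches(self):
        null = np.full(30, 0.5)
        p_bad, _ = _null_pvalue(0.4, null, classification=True)
        assert p_bad == 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            p_good, _ = _null_pvalue(0.9, null, classification=True)
        assert p_good == pytest.approx(1 / 31)

    def test_regression_uses_lower_tail(self):
        null = np.linspace(1.0, 2.0, 50)  # null MSEs
        p_small, _ = _null_pvalue(0.1, null, classification=False)
        p_large, _ = _null_pvalue(3.0, null, classification=False)
        assert p_small < 0.05 < p_large

    def test_separated_groups_significant(self, rng):
        X = rng.normal(size=(10, 6))
        X[5:] += 5.0
        y, _ = encode_labels(["a"] * 5 + ["b"] * 5)
        res = permutation_test(X, y, 1, n_perm=100, seed=11)
        assert res.observed == 1.0
        assert res.p_value < 0.05
        assert len(res.null_values) == 100

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(8, 4))
        y, _ = encode_labels(["a", "b"] * 4)
        r1 = permutation_test(X, y, 1, n_perm=50, seed=7)
        r2 = permutation_test(X, y, 1, n_perm=50, seed=7)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)


class TestVIP:
    def test_single_predictor_vip_is_one(self):
        x = np.arange(5.0)[:, None] + np.random.default_rng(0).normal(size=(5, 1)) * 0.1
        y = np.arange(5.0)
        Z, _ = autoscale(x)
        model = nipals_pls(Z, y - y.mean(), 1)
        table = vip(model)
        np.testing.assert_allclose(table.vip, [1.0], atol=1e-12)

    def test_identical_copies_all_one(self, rng):
        x = rng.normal(size=6)
        X = np.column_stack([x, x, x])
        y = x + rng.normal(size=6) * 0.1
        Z, _ = autoscale(X)
        model = nipals_pls(Z, y - y.mean(), 1)
        np.testing.assert_allclose(vip(model).vip, 1.0, atol=1e-10)

    def test_normalization_on_random_fits(self, rng):
        for _ in range(10):
            X = rng.normal(size=(10, 7))
            y = rng.normal(size=10)
            A = int(rng.integers(1, 5))
            Z, _ = autoscale(X)
            model = nipals_pls(Z, y - y.mean(), A)
            v = vip(model).vip
            assert np.sum(v**2) == pytest.approx(7, abs=1e-8)

    def test_signal_predictors_rank_above_noise(self, rng):
        X = rng.normal(size=(20, 10))
        y = X[:, :3] @ np.array([1.0, 1.0, 1.0]) + 0.3 * rng.normal(size=20)
        Z, _ = autoscale(X)
        model = nipals_pls(Z, y - y.mean(), 2)
        v = vip(model).vip
        assert v[:3].min() > v[3:].max()

    def test_requires_unrotated_model(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model, _ = fit(X, y, 2)
        with pytest.raises(PLSError):
            vip(orthogonalize(model))


class TestBundles:
    def test_plsda_end_to_end_recovers_signature(self, rng):
        X = rng.normal(size=(10, 12))
        X[5:, :3] += 4.0
        labels = ["ctrl"] * 5 + ["case"] * 5
        res = fit_plsda(X, labels, n_perm=100, seed=3)
        assert res.accuracy >= 0.9
        assert res.permutation.p_value < 0.05
        assert res.model.orthogonalized
        key = set(res.vip_table.key_predictors)
        assert {"x0", "x1", "x2"} <= key

    def test_constant_labels_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(PLSError):
            fit_plsda(X, ["a"] * 8, n_perm=20, seed=1)

    def test_label_swap_flips_lv1_loadings_only(self, rng):
        X = rng.normal(size=(10, 6))
        X[5:, :2] += 3.0
        la = ["a"] * 5 + ["b"] * 5
        lb = ["b"] * 5 + ["a"] * 5
        r1 = fit_plsda(X, la, n_perm=50, seed=5)
        r2 = fit_plsda(X, lb, n_perm=50, seed=5)
        np.testing.assert_allclose(r1.lv1_loadings, -r2.lv1_loadings, atol=1e-10)
        assert r1.accuracy == r2.accuracy
        np.testing.assert_allclose(r1.vip_table.vip, r2.vip_table.vip, atol=1e-10)

    def test_missing_and_constant_predictors_dropped(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        X.loc[2, "b"] = np.nan
        X["c"] = 0.0
        labels = ["x", "y"] * 4
        res = fit_plsda(X, labels, n_perm=20, seed=2)
        assert set(res.dropped_predictors) == {"b", "c"}
        assert res.predictor_names == ["a", "d"]

    def test_plsr_noiseless_linear_response(self, rng):
        X = rng.normal(size=(9, 4))
        y = 3.0 * X[:, 0]
        res = fit_plsr(X, y, n_perm=50, seed=9)
        assert res.q2 > 0.99
        assert res.permutation.p_value < 0.05

    def test_plsr_null_response_not_significant(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(400 + s)
            X = r.normal(size=(12, 8))
            y = r.normal(size=12)
            res = fit_plsr(X, y, n_perm=100, seed=500 + s)
            hits += res.permutation.p_value < 0.05
        assert hits <= 2

    def test_plsr_needs_three_distinct_values(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(PLSError):
            fit_plsr(X, [1.0, 2.0] * 4, n_perm=20, seed=1)
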