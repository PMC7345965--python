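"""NIPALS PLS1 classifier: algebraic identities, oracles, VIP properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aastone import classify, compute_vip, fit_plsda, predict_scores, transform


def _random_problem(rng, n=30, p=6, informative=True):
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.5).astype(int)
    while len(np.unique(y)) < 2:
        y = (rng.random(n) < 0.5).astype(int)
    if informative:
        X[:, 0] += 2.0 * y
    return X, y


class TestFitBasics:
    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(X, np.zeros(10), 1)

    def test_excess_lv_request_truncated_with_warning(self, rng):
        X, y = _random_problem(rng, n=8, p=3)
        with pytest.warns(UserWarning, match="truncat"):
            model = fit_plsda(X, y, 20)
        assert model.n_lv <= 3

    def test_deterministic_fit(self, rng):
        X, y = _random_problem(rng)
        m1 = fit_plsda(X, y, 3)
        m2 = fit_plsda(X, y, 3)
        np.testing.assert_array_equal(m1.B, m2.B)
        np.testing.assert_array_equal(m1.T, m2.T)

    def test_training_prediction_consistency(self, rng):
        """Prediction via B equals the sequential score expansion: on the
        training data, y_mean + sum_a t_a q_a."""
        X, y = _random_problem(rng)
        model = fit_plsda(X, y, 4)
        via_scores = model.y_mean + model.T @ model.q
        via_coefs = predict_scores(model, X)
        np.testing.assert_allclose(via_coefs, via_scores, atol=1e-10)


class TestAlgebraicIdentities:
    def test_one_column_pls_equals_simple_regression(self, rng):
        """With a single predictor, 1-LV PLS is univariate least squares."""
        x = rng.normal(size=(25, 1))
        y = (x[:, 0] + rng.normal(scale=0.5, size=25) > 0).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = fit_plsda(x, y, 1, scaling="center")
        xc = x[:, 0] - x[:, 0].mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        pred_ols = y.mean() + slope * xc
        np.testing.assert_allclose(predict_scores(model, x), pred_ols, atol=1e-10)

    @pytest.mark.parametrize("p", [3, 5, 8])
    def test_full_rank_pls_matches_least_squares_oracle(self, rng, p):
        """At A = rank(X), PLS fitted values equal the multiple least-squares
        fit (intercept + centered X) within 1e-8."""
        X, y = _random_problem(rng, n=40, p=p)
        model = fit_plsda(X, y, p, scaling="center")
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        pred_ls = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict_scores(model, X), pred_ls, atol=1e-8)

    def test_score_columns_mutually_orthogonal(self, rng):
        X, y = _random_problem(rng, n=50, p=10)
        T = fit_plsda(X, y, 6).T
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(len(norms))
        assert np.abs(off).max() < 1e-8

    def test_weight_columns_orthonormal(self, rng):
        X, y = _random_problem(rng, n=50, p=10)
        W = fit_plsda(X, y, 6).W
        np.testing.assert_allclose(W.T @ W, np.eye(6), atol=1e-8)

    def test_transform_reproduces_training_scores(self, rng):
        X, y = _random_problem(rng)
        model = fit_plsda(X, y, 3)
        np.testing.assert_allclose(transform(model, X), model.T, atol=1e-8)

    def test_mean_vector_predicts_class_prior(self, rng):
        X, y = _random_problem(rng)
        model = fit_plsda(X, y, 2)
        pred = predict_scores(model, X.mean(axis=0))
        np.testing.assert_allclose(pred, model.y_mean, atol=1e-10)


class TestCrossCheck:
    def test_matches_independent_pls_implementation(self, rng):
        """Predictions agree with scikit-learn's PLSRegression on the same
        standardized data at every component count."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(rng, n=35, p=8)
        for a in (1, 2, 4):
            model = fit_plsda(X, y, a, scaling="auto")
            ref = sklearn.PLSRegression(n_components=a, scale=True)
            ref.fit(X, y.astype(float))
            np.testing.assert_allclose(
                predict_scores(model, X), ref.predict(X).ravel(), atol=1e-8
            )


class TestClassify:
    def test_threshold_rule_and_tie_break(self):
        labels = classify(np.array([0.9, 0.1, 0.5]), threshold=0.5)
        assert labels.tolist() == [1, 0, 0]  # exact threshold -> control

    def test_separable_clusters_perfectly_classified(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] += 6.0 * y  # 6-SD separation
        model = fit_plsda(X, y, 2)
        assert (classify(predict_scores(model, X)) == y).all()


class TestVIP:
    @given(seed=st.integers(0, 10_000), n_lv=st.integers(1, 4))
    @settings(max_examples=30, deadline=None)
    def test_mean_squared_vip_is_one(self, seed, n_lv):
        """Algebraic identity: sum(VIP^2) = p for every fitted model."""
        rng = np.random.default_rng(seed)
        X, y = _random_problem(rng, n=20, p=6)
        model = fit_plsda(X, y, n_lv)
        vip = compute_vip(model)
        assert abs((vip**2).mean() - 1.0) < 1e-10

    def test_informative_analyte_has_max_vip(self, rng):
        """One strong analyte among pure noise dominates the VIP ranking."""
        n, p = 200, 10
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, p))
        X[:, 3] += 5.0 * y
        model = fit_plsda(X, y, 2)
        assert int(np.argmax(compute_vip(model))) == 3

    def test_duplicated_informative_columns_share_vip(self, rng):
        n = 100
        y = np.repeat([0, 1], n // 2)
        signal = 3.0 * y + rng.normal(scale=0.5, size=n)
        X = np.column_stack([signal, signal])
        model = fit_plsda(X, y, 1)
        vip = compute_vip(model)
        np.testing.assert_allclose(vip[0], vip[1], atol=1e-10)

    def test_vip_equals_direct_formula_evaluation(self, rng):
        """Independent recomputation of the VIP formula from model pieces."""
        X, y = _random_problem(rng, n=30, p=7)
        model = fit_plsda(X, y, 3)
        ssy = np.array(
            [model.q[a] ** 2 * (model.T[:, a] @ model.T[:, a]) for a in range(3)]
        )
        expected = np.sqrt(
            7 * sum(ssy[a] * model.W[:, a] ** 2 for a in range(3)) / ssy.sum()
        )
        np.testing.assert_allclose(compute_vip(model), expected, atol=1e-12)
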