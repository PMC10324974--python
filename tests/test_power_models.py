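import numpy as np
import pandas as pd
import pytest

from stridepower.power_models import (ElasticNetPower, NeuralNetPower,
                                      Normalizer, select_best_model)


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestNormalizer:
    def test_development_statistics(self, rng):
        X = rng.normal(loc=5.0, scale=3.0, size=(500, 4))
        norm = Normalizer.fit(X)
        Z = norm.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_test_data_uses_development_statistics(self, rng):
        X = rng.normal(size=(100, 2))
        norm = Normalizer.fit(X)
        Xt = rng.normal(loc=10.0, size=(50, 2))
        Z = norm.transform(Xt)
        np.testing.assert_allclose(Z, (Xt - X.mean(0)) / X.std(0))

    def test_constant_column_warns_and_zeroes(self, rng):
        X = np.column_stack([rng.normal(size=50), np.full(50, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            norm = Normalizer.fit(X, feature_names=["a", "const"])
        Z = norm.transform(X)
        np.testing.assert_array_equal(Z[:, 1], 0.0)


class TestElasticNetOracles:
    def test_lambda_zero_equals_least_squares(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        res = ElasticNetPower(y, X).fit(lambda_=0.0)
        Z = _standardize(X)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(5), Z]), y, rcond=None)
        np.testing.assert_allclose(res.intercept, beta[0], atol=1e-8)
        np.testing.assert_allclose(res.beta, beta[1:], atol=1e-8)

    def test_gamma_zero_matches_ridge_closed_form(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        lam = 7.3
        res = ElasticNetPower(y, X, gamma=0.0).fit(lambda_=lam)
        Z = _standardize(X)
        # objective RSS + (lambda/2)||b||^2 -> (Z'Z + lambda/2 I)^-1 Z'yc
        ref = np.linalg.solve(Z.T @ Z + lam / 2 * np.eye(4),
                              Z.T @ (y - y.mean()))
        np.testing.assert_allclose(res.beta, ref, atol=1e-8)

    def test_objective_value_matches_direct_minimization(self, rng):
        from scipy.optimize import minimize
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.normal(size=40) * 0.1
        lam, gam = 5.0, 0.5
        res = ElasticNetPower(y, X, gamma=gam).fit(lambda_=lam)
        Z = _standardize(X)

        def objective(p):
            r = y - p[0] - Z @ p[1:]
            return r @ r + lam * np.sum((1 - gam) / 2 * p[1:] ** 2
                                        + gam * np.abs(p[1:]))

        direct = minimize(objective, np.zeros(5), method="Nelder-Mead",
                          options=dict(maxiter=40_000, xatol=1e-10, fatol=1e-12))
        mine = objective(np.concatenate([[res.intercept], res.beta]))
        assert mine <= direct.fun + 1e-6

    def test_full_shrinkage_limit(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(loc=100.0, size=50)
        res = ElasticNetPower(y, X, gamma=1.0).fit(lambda_=1e9)
        np.testing.assert_array_equal(res.beta, 0.0)
        assert res.intercept == pytest.approx(y.mean())

    def test_sparsity_monotone_along_path(self, rng):
        X = rng.normal(size=(80, 10))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=80) * 0.2
        m = ElasticNetPower(y, X)
        grid = np.logspace(np.log10(m.lambda_max()), np.log10(m.lambda_max()) - 4, 20)
        nnz = [np.count_nonzero(m.fit(lambda_=lam).beta) for lam in grid]
        # walking the grid down in lambda, the support can only grow
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))


class TestElasticNetRecovery:
    def test_support_and_coefficients_recovered(self):
        rng = np.random.default_rng(42)
        n, p = 5000, 20
        X = rng.normal(size=(n, p))
        true_beta = np.zeros(p)
        true_beta[:5] = [3.0, -2.0, 1.5, 2.5, -1.0]
        y = X @ true_beta
        y = y + rng.normal(size=n) * 0.05 * y.std()
        res = ElasticNetPower(y, X).fit(seed=0)
        support = set(np.flatnonzero(res.beta != 0.0).tolist())
        assert support == {0, 1, 2, 3, 4}
        rel_err = np.abs((res.beta[:5] - true_beta[:5]) / true_beta[:5])
        assert rel_err.max() < 0.10

    def test_grouped_cv_runs(self, rng):
        X = rng.normal(size=(200, 5))
        y = X[:, 0] + rng.normal(size=200) * 0.1
        groups = np.repeat(np.arange(10), 20)
        res = ElasticNetPower(y, X).fit(selection="1se", groups=groups)
        assert res.cv_table is not None
        assert abs(res.params.iloc[0]) > 0.5


class TestElasticNetInterface:
    def test_predict_matches_hand_computation(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.0, 1.0, 0.0, 1.0]})
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = ElasticNetPower(y, X).fit(lambda_=0.0)
        x_new = pd.DataFrame({"a": [2.5], "b": [1.0]})
        z = (x_new.to_numpy()[0] - X.to_numpy().mean(0)) / X.to_numpy().std(0)
        expected = res.intercept + z @ res.beta
        assert res.predict(x_new)[0] == pytest.approx(expected)

    def test_constant_prediction_with_zero_beta(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        res = ElasticNetPower(y, X, gamma=1.0).fit(lambda_=1e9)
        np.testing.assert_allclose(res.predict(rng.normal(size=(7, 3))),
                                   res.intercept)

    def test_feature_name_mismatch_raises(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = ElasticNetPower(rng.normal(size=30), X).fit(lambda_=1.0)
        with pytest.raises(KeyError):
            res.predict(pd.DataFrame(rng.normal(size=(3, 2)),
                                     columns=["a", "c"]))

    def test_prediction_row_order_invariant(self, rng):
        X = rng.normal(size=(40, 3))
        res = ElasticNetPower(rng.normal(size=40), X).fit(lambda_=1.0)
        Xt = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        np.testing.assert_allclose(res.predict(Xt)[perm], res.predict(Xt[perm]))

    def test_summary_mentions_key_quantities(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["f1", "f2", "f3"])
        res = ElasticNetPower(rng.normal(size=50), X).fit(lambda_=1.0)
        text = res.summary()
        assert "lambda" in text and "gamma" in text


class TestNeuralNet:
    def test_parameter_count(self, rng):
        nn = NeuralNetPower(rng.normal(size=100), rng.normal(size=(100, 7)))
        assert nn.n_params == 10 * (7 + 1) + 11

    def test_realizable_target_recovered(self, rng):
        # data generated by a random same-architecture network, no noise
        k, n = 4, 800
        theta_true = rng.normal(scale=0.5, size=10 * (k + 1) + 11)
        X = rng.normal(size=(n, k))
        y, _ = NeuralNetPower._forward(theta_true, X, 10)
        res = NeuralNetPower(y, X).fit(seed=2, max_epochs=200)
        train_mse = np.mean((y - res.predict(X)) ** 2)
        assert train_mse < 1e-3 * y.var()

    def test_linear_target_generalizes(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        y = 2.0 * X[:, 0] + rng.normal(size=n) * 0.1
        res = NeuralNetPower(y, X, scheme="NN15").fit(seed=1, max_epochs=60)
        Xt = rng.normal(size=(500, 3))
        yt = 2.0 * Xt[:, 0]
        pred = res.predict(Xt)
        r2 = 1 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2)
        assert r2 > 0.95

    def test_same_seed_identical_weights(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(size=200) * 0.2
        a = NeuralNetPower(y, X).fit(seed=7, max_epochs=20)
        b = NeuralNetPower(y, X).fit(seed=7, max_epochs=20)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_scheme_split_fractions(self, rng):
        assert NeuralNetPower(rng.normal(size=100), rng.normal(size=(100, 2)),
                              scheme="NN35").scheme == "NN35"
        with pytest.raises(ValueError):
            NeuralNetPower(rng.normal(size=100), rng.normal(size=(100, 2)),
                           scheme="NN99")

    def test_too_few_rows_rejected(self, rng):
        nn = NeuralNetPower(rng.normal(size=20), rng.normal(size=(20, 2)))
        with pytest.raises(ValueError):
            nn.fit()


class TestSelectBestModel:
    class _Stub:
        def __init__(self, offset):
            self.offset = offset

        def predict(self, X):
            return np.zeros(len(X)) + self.offset

    def test_single_candidate_returned(self):
        X, y = np.zeros((10, 1)), np.zeros(10)
        label, _ = select_best_model({"EN": self._Stub(0.0)}, X, y)
        assert label == "EN"

    def test_lowest_mae_wins(self):
        X, y = np.zeros((10, 1)), np.zeros(10)
        label, maes = select_best_model(
            {"EN": self._Stub(2.0), "NN15": self._Stub(0.5),
             "NN35": self._Stub(1.0)}, X, y)
        assert label == "NN15"
        assert maes["EN"] == pytest.approx(2.0)

    def test_tie_prefers_elastic_net(self):
        X, y = np.zeros((10, 1)), np.zeros(10)
        label, _ = select_best_model(
            {"NN15": self._Stub(1.0), "EN": self._Stub(1.0)}, X, y)
        assert label == "EN"
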