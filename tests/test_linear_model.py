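"""Elastic-net solver: closed forms, KKT conditions, CV selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from finclock import (
    ElasticNetCD,
    ElasticNetConfig,
    LogisticElasticNetCD,
    cv_select_lambda,
    fit_binomial,
    fit_gaussian,
    lambda_path,
)
from finclock.simulate import SimulationConfig, simulate_dataset


def soft_threshold(x, thr):
    return np.sign(x) * max(abs(x) - thr, 0.0)


@pytest.fixture
def xy10():
    """Fixed 10-sample univariate pair, x standardized (mean 0, 1/n var 1)."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=10)
    x = (x - x.mean()) / x.std()
    y = 0.8 * x + rng.normal(size=10) * 0.3
    return x, y


class TestGaussianClosedForms:
    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.6])
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0])
    def test_univariate_soft_threshold_solution(self, xy10, lam, alpha):
        x, y = xy10
        est = ElasticNetCD(alpha=alpha, lam=lam, standardize=False,
                           tol=1e-12).fit(x[:, None], y)
        yc = y - y.mean()
        expected = soft_threshold(x @ yc / 10.0, lam * alpha) / (
            1.0 + lam * (1.0 - alpha)
        )
        assert est.coef_[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_penalty_matches_weighted_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=30)
        w = rng.uniform(0.5, 2.0, 30)
        est = ElasticNetCD(alpha=0.5, lam=0.0, tol=1e-12).fit(
            X, y, sample_weight=w
        )
        Xi = np.column_stack([np.ones(30), X])
        W = np.diag(w)
        ols = np.linalg.solve(Xi.T @ W @ Xi, Xi.T @ W @ y)
        assert est.intercept_ == pytest.approx(ols[0], abs=1e-6)
        np.testing.assert_allclose(est.coef_, ols[1:], atol=1e-6)

    def test_above_lambda_max_gives_null_model(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        w = rng.uniform(0.2, 1.0, 20)
        path = lambda_path(X, y, w, ElasticNetConfig())
        for lam in (path[0], 2.0 * path[0]):
            est = ElasticNetCD(alpha=0.5, lam=float(lam)).fit(
                X, y, sample_weight=w
            )
            assert est.n_nonzero_ == 0
            assert est.intercept_ == pytest.approx(
                np.average(y, weights=w), abs=1e-12
            )

    def test_constant_response_gives_weighted_mean(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.full(12, 3.3)
        est = ElasticNetCD(lam=0.1).fit(X, y)
        assert est.n_nonzero_ == 0
        assert est.intercept_ == pytest.approx(3.3)


class TestKKT:
    @staticmethod
    def kkt_residuals(X, y, w, est):
        """Stationarity residuals of the fitted model, on the penalty scale."""
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
        xm = w @ X
        Xc = X - xm
        if est.standardize:
            s = np.sqrt(w @ Xc**2)
            s[s == 0] = 1.0
            Xs = Xc / s
        else:
            s = np.ones(X.shape[1])
            Xs = Xc
        b = est.coef_ * s  # coefficients on the penalized scale
        r = y - est.intercept_ - X @ est.coef_
        g = (w * r) @ Xs
        l1 = est.lambda_ * est.alpha
        l2 = est.lambda_ * (1.0 - est.alpha)
        nz = b != 0
        active = np.abs(g[nz] - l1 * np.sign(b[nz]) - l2 * b[nz])
        inactive = np.maximum(np.abs(g[~nz]) - l1, 0.0)
        return active, inactive

    @pytest.mark.parametrize("standardize", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stationarity_within_tolerance(self, standardize, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 40))
        y = X[:, 0] - 0.5 * X[:, 5] + rng.normal(size=25) * 0.5
        w = rng.uniform(0.3, 1.5, 25)
        tol = 1e-9
        path = lambda_path(X, y, w, ElasticNetConfig(standardize=standardize))
        lam = float(path[30])
        est = ElasticNetCD(alpha=0.5, lam=lam, tol=tol,
                           standardize=standardize).fit(X, y, sample_weight=w)
        active, inactive = self.kkt_residuals(X, y, w, est)
        assert active.size > 0
        assert np.all(active <= 10 * tol)
        assert np.all(inactive <= 10 * tol)


class TestWeightSemantics:
    def test_weight_scaling_invariance(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        w = rng.uniform(0.1, 1.0, 15)
        a = ElasticNetCD(lam=0.05).fit(X, y, sample_weight=w)
        b = ElasticNetCD(lam=0.05).fit(X, y, sample_weight=17.0 * w)
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=0, atol=1e-12)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-12)

    def test_half_weight_duplicate_equals_unit_single(self, rng):
        """A +/-2-accuracy sample at weight 0.5 entered twice must match the
        same sample entered once at weight 1.0."""
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        w_single = np.ones(12)
        X_dup = np.vstack([X, X[-1]])
        y_dup = np.append(y, y[-1])
        w_dup = np.append(np.ones(11), [0.5, 0.5])
        a = ElasticNetCD(lam=0.08, tol=1e-12).fit(X, y, sample_weight=w_single)
        b = ElasticNetCD(lam=0.08, tol=1e-12).fit(
            X_dup, y_dup, sample_weight=w_dup
        )
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-8)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-8)


class TestBinomial:
    def test_huge_penalty_gives_class_log_odds(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.array([1] * 13 + [0] * 7)
        est = LogisticElasticNetCD(lam=100.0).fit(X, y)
        assert est.n_nonzero_ == 0
        assert est.intercept_ == pytest.approx(np.log(13 / 7), abs=1e-8)

    def test_balanced_labels_zero_features_give_half_probability(self):
        X = np.zeros((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            est = LogisticElasticNetCD(lam=0.1).fit(X, y)
        assert est.intercept_ == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(est.predict_proba(X)[:, 1], 0.5)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            LogisticElasticNetCD(lam=0.1).fit(X, np.ones(10))

    def test_matches_direct_penalized_deviance_minimizer(self):
        """Independent oracle: minimize the penalized deviance directly via
        a smooth split-variable reformulation (b = u - v, u, v >= 0)."""
        rng = np.random.default_rng(42)
        n = 20
        X = rng.normal(size=(n, 2))
        proj = X[:, 0] + 0.5 * X[:, 1]
        X[:, 0] += np.sign(proj) * 0.5  # enforce a clear separation margin
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(float)  # separable
        lam, alpha = 0.02, 0.5

        def objective(params):
            b0 = params[0]
            u, v = params[1:3], params[3:5]
            b = u - v
            eta = b0 + X @ b
            # log(1 + e^eta) - y*eta, numerically stable
            ll = np.logaddexp(0.0, eta) - y * eta
            pen = lam * (alpha * np.sum(u + v)
                         + 0.5 * (1 - alpha) * np.sum(b**2))
            return ll.mean() + pen

        res = minimize(
            objective, np.zeros(5), method="L-BFGS-B",
            bounds=[(None, None)] + [(0, None)] * 4,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 20000},
        )
        b_ref = res.x[1:3] - res.x[3:5]
        est = LogisticElasticNetCD(
            alpha=alpha, lam=lam, standardize=False, tol=1e-12
        ).fit(X, y)
        np.testing.assert_allclose(est.coef_, b_ref, atol=1e-4)
        assert est.intercept_ == pytest.approx(res.x[0], abs=1e-4)
        # all training predictions on the correct side of 0.5
        p = est.predict_proba(X)[:, 1]
        assert np.all((p > 0.5) == (y == 1))

    def test_label_flip_gives_complementary_probabilities(self, rng):
        X = rng.normal(size=(24, 10))
        y = (X[:, 0] + rng.normal(size=24) * 0.5 > 0).astype(int)
        a = LogisticElasticNetCD(lam=0.05, tol=1e-10).fit(X, y)
        b = LogisticElasticNetCD(lam=0.05, tol=1e-10).fit(X, 1 - y)
        pa = a.predict_proba(X)[:, 1]
        pb = b.predict_proba(X)[:, 1]
        np.testing.assert_allclose(pa, 1.0 - pb, atol=1e-7)


class TestLambdaPath:
    def test_log_even_spacing_and_descent(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        path = lambda_path(X, y, None, ElasticNetConfig(n_lambda=50))
        assert len(path) == 50
        assert np.all(np.diff(path) < 0)
        ratios = path[1:] / path[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_univariate_lambda_max_matches_hand_value(self, xy10):
        x, y = xy10
        alpha = 0.5
        path = lambda_path(
            x[:, None], y, None,
            ElasticNetConfig(alpha=alpha, standardize=False),
        )
        expected = abs(x @ (y - y.mean())) / (10.0 * alpha)
        assert path[0] == pytest.approx(expected, rel=1e-8)

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            lambda_path(X, np.ones(10), None, ElasticNetConfig())


class TestCVSelection:
    def test_loo_is_seed_invariant(self, rng):
        X = rng.normal(size=(20, 15))
        y = X[:, 0] + rng.normal(size=20) * 0.2
        lam1, err1 = cv_select_lambda(X, y, seed=0)
        lam2, err2 = cv_select_lambda(X, y, seed=99)
        assert lam1 == lam2
        np.testing.assert_array_equal(err1, err2)

    def test_pure_noise_selects_heavy_shrinkage(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 40))
        y = rng.normal(size=30)
        cfg = ElasticNetConfig()
        path = lambda_path(X, y, None, cfg)
        lam, _ = cv_select_lambda(X, y, config=cfg, lambdas=path)
        assert lam >= np.quantile(path, 0.75)

    def test_signal_data_selects_interior_lambda(self):
        for seed in (0, 1, 2):
            beta, sheet, _ = simulate_dataset(SimulationConfig(
                n_samples=40, n_age_cpgs=60, n_sex_cpgs=0, n_null_cpgs=300,
                seed=seed,
            ))
            from finclock import AgeTransform

            X = beta.samples_by_cpgs()
            y = AgeTransform().transform(
                sheet.data["age"].to_numpy(dtype=float)
            )
            cfg = ElasticNetConfig()
            path = lambda_path(X, y, None, cfg)
            lam, err = cv_select_lambda(X, y, config=cfg, lambdas=path)
            i = int(np.argmin(err))
            assert 0 < i < len(path) - 1

    def test_kfold_folds_deterministic_from_seed(self, rng):
        X = rng.normal(size=(24, 10))
        y = X[:, 1] + rng.normal(size=24) * 0.3
        lam1, _ = cv_select_lambda(X, y, n_folds=6, seed=3)
        lam2, _ = cv_select_lambda(X, y, n_folds=6, seed=3)
        assert lam1 == lam2


class TestFunctionalWrappers:
    def test_fit_gaussian_returns_named_sparse_map(self, rng):
        X = rng.normal(size=(20, 5))
        y = 2.0 * X[:, 2] + rng.normal(size=20) * 0.1
        res = fit_gaussian(X, y, lam=0.1, feature_ids=list("abcde"))
        assert res.n_nonzero == len(res.coefficients)
        assert "c" in res.coefficients
        assert res.converged

    def test_fit_binomial_flags_separation(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        res = fit_binomial(X, y, lam=1e-6, config=ElasticNetConfig(tol=1e-6))
        assert res.separation

    def test_probabilities_through_logistic(self, rng):
        X = rng.normal(size=(16, 3))
        y = (X[:, 0] > 0).astype(int)
        est = LogisticElasticNetCD(lam=0.2).fit(X, y)
        p = est.predict_proba(X)
        np.testing.assert_allclose(
            p[:, 1], expit(est.intercept_ + X @ est.coef_)
        )
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
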