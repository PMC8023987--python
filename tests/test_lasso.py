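import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from trajmix import lasso
from trajmix.lasso import (
    LassoResult,
    LassoTask,
    add_interactions,
    build_weighted_response,
    cv_select_lambda,
    default_lambda_grid,
    fit_lasso_cv,
    kkt_violation,
    lambda_max,
    lasso_path,
    objective,
    pool_over_imputations,
    predicted_probability_grid,
    _standardize,
)


def _make_task(n=300, p=6, signal=(1.0, -0.8), seed=0, weights=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    eta = -0.5 + X[:, 0] * signal[0] + X[:, 1] * signal[1] \
        if signal else np.full(n, -0.5)
    y = (rng.random(n) < expit(eta)).astype(float)
    w = np.ones(n) if weights is None else weights
    return LassoTask(
        X=X, y=y, w=w, feature_names=[f"x{j}" for j in range(p)],
        patient_ids=np.arange(n).astype(str), modal_severe=y.astype(int),
    )


class TestWeightedResponse:
    def _fit_stub(self, probs):
        from trajmix.gmm import GMMSpec

        class Stub:
            spec = GMMSpec(n_classes=2)
            posterior = pd.DataFrame(
                {"class_1": 1 - np.asarray(probs),
                 "class_2": np.asarray(probs)},
                index=pd.Index([f"p{i}" for i in range(len(probs))],
                               name="patient_id"))
        return Stub()

    def test_degenerate_posterior_single_row(self):
        out = build_weighted_response(self._fit_stub([1.0]))
        assert len(out) == 1
        assert out.iloc[0]["y"] == 1.0 and out.iloc[0]["w"] == 1.0

    def test_fractional_rows(self):
        out = build_weighted_response(self._fit_stub([0.25]))
        assert [(r.y, r.w) for r in out.itertuples()] == [
            (1.0, 0.25), (0.0, 0.75)]

    def test_one_hot_reduces_to_modal_classification(self):
        out = build_weighted_response(self._fit_stub([1.0, 0.0, 1.0]))
        assert len(out) == 3
        assert (out["w"] == 1.0).all()
        assert list(out["y"]) == [1.0, 0.0, 1.0]

    def test_three_class_fit_rejected(self):
        from trajmix.gmm import GMMSpec

        class Stub:
            spec = GMMSpec(n_classes=3)
        with pytest.raises(ValueError):
            build_weighted_response(Stub())


class TestPath:
    def test_lambda_max_zeroes_all_slopes(self):
        task = _make_task()
        Xs, _, _ = _standardize(task.X, task.w)
        lmax = lambda_max(Xs, task.y, task.w)
        grid, b0s, coefs = lasso_path(task, [lmax * 1.0001, lmax * 2])
        assert np.all(coefs == 0.0)

    def test_unpenalized_matches_weighted_irls(self):
        """lambda=0 equals the weighted logistic ML fit (statsmodels GLM
        with variance weights as the oracle)."""
        rng = np.random.default_rng(1)
        task = _make_task(n=400, seed=1, weights=rng.random(400) + 0.2)
        grid, b0s, coefs = lasso_path(task, [1e-10], check_kkt=False)
        X = sm.add_constant(task.X)
        glm = sm.GLM(task.y, X, family=sm.families.Binomial(),
                     var_weights=task.w).fit()
        assert b0s[0] == pytest.approx(glm.params[0], abs=1e-4)
        assert np.allclose(coefs[0], glm.params[1:], atol=1e-4)

    def test_kkt_along_path(self):
        task = _make_task(n=250, seed=2)
        Xs, _, _ = _standardize(task.X, task.w)
        grid = default_lambda_grid(lambda_max(Xs, task.y, task.w), n=40)
        lasso_path(task, grid, check_kkt=True)  # raises on violation
        # explicit re-check at a mid-path solution
        _, b0s, coefs = lasso_path(task, grid, check_kkt=False)
        i = 20
        sd = Xs.std(axis=0)
        viol = kkt_violation(Xs, task.y, task.w, grid[i],
                             b0s[i] + coefs[i] @ (task.X.mean(0)),
                             coefs[i] * task.X.std(0))
        assert viol <= grid[i] + 1e-5

    def test_sklearn_cross_check(self):
        """Equal-weight instance against scikit-learn's saga L1 solver."""
        from sklearn.linear_model import LogisticRegression
        task = _make_task(n=500, seed=3)
        Xs, mu, sd = _standardize(task.X, task.w)
        task_std = LassoTask(X=Xs, y=task.y, w=task.w,
                             feature_names=task.feature_names,
                             patient_ids=task.patient_ids,
                             modal_severe=task.modal_severe)
        lam = 0.02
        _, b0s, coefs = lasso_path(task_std, [lam])
        skl = LogisticRegression(
            penalty="l1", C=1.0 / (len(task.y) * lam), solver="saga",
            tol=1e-10, max_iter=50_000).fit(Xs, task.y)
        assert np.allclose(coefs[0], skl.coef_[0], atol=2e-3)
        assert b0s[0] == pytest.approx(float(skl.intercept_[0]), abs=2e-3)

    def test_local_optimality(self):
        task = _make_task(n=200, seed=4)
        Xs, _, _ = _standardize(task.X, task.w)
        lam = 0.03
        task_std = LassoTask(X=Xs, y=task.y, w=task.w,
                             feature_names=task.feature_names,
                             patient_ids=task.patient_ids,
                             modal_severe=task.modal_severe)
        _, b0s, coefs = lasso_path(task_std, [lam])
        f0 = objective(Xs, task.y, task.w, lam, b0s[0], coefs[0])
        rng = np.random.default_rng(0)
        for _ in range(100):
            pert = coefs[0] + rng.normal(0, 0.01, coefs[0].shape)
            fb = objective(Xs, task.y, task.w, lam,
                           b0s[0] + rng.normal(0, 0.01), pert)
            assert f0 <= fb + 1e-12

    def test_sparsity_nonincreasing_in_lambda(self):
        task = _make_task(n=300, seed=5)
        grid, b0s, coefs = lasso_path(task)
        nnz = (coefs != 0).sum(axis=1)
        # grid descends, so non-zeros grow along the path
        assert np.all(np.diff(nnz) >= 0) or nnz[-1] >= nnz[0]

    def test_single_outcome_class_rejected(self):
        task = _make_task(n=50, signal=None, seed=6)
        task.y[:] = 1.0
        with pytest.raises(ValueError):
            lasso_path(task)


class TestCV:
    def test_separable_data_reaches_auc_one(self):
        rng = np.random.default_rng(7)
        n = 120
        X = rng.normal(0, 1, (n, 3))
        y = (X[:, 0] > 0).astype(float)
        task = LassoTask(X=X, y=y, w=np.ones(n),
                         feature_names=["a", "b", "c"],
                         patient_ids=np.arange(n).astype(str),
                         modal_severe=y.astype(int))
        lam, curve, grid = cv_select_lambda(task, n_folds=5, loss="auc",
                                            seed=0)
        assert curve.min() == pytest.approx(0.0, abs=1e-9)

    def test_reproducible_given_seed(self):
        task = _make_task(n=200, seed=8)
        a = cv_select_lambda(task, 5, "deviance", seed=3)
        b = cv_select_lambda(task, 5, "deviance", seed=3)
        assert a[0] == b[0] and np.allclose(a[1], b[1])

    def test_pure_noise_selects_near_empty_model(self):
        """With independent noise predictors the minimum-CV rule keeps at
        most a stray predictor or two; it is not forced to the empty model
        (that is the 1-SE rule, deliberately not used here)."""
        nnz = []
        for seed in range(20):
            task = _make_task(n=200, p=5, signal=None, seed=100 + seed)
            res = fit_lasso_cv(task, n_folds=10, loss="deviance", seed=seed)
            nnz.append(int((res.coef != 0).sum()))
        assert np.mean(nnz) <= 1.5
        assert sum(k == 0 for k in nnz) >= 5

    def test_loss_functions_agree_on_signal_predictors(self):
        """AUC- and deviance-selected models both retain the generating
        predictors on clearly informative data."""
        agree = 0
        for seed in range(5):
            task = _make_task(n=400, signal=(1.2, -1.0), seed=300 + seed)
            r_auc = fit_lasso_cv(task, n_folds=5, loss="auc", seed=seed)
            r_dev = fit_lasso_cv(task, n_folds=5, loss="deviance", seed=seed)
            both = ({"x0", "x1"} <=
                    set(r_auc.coef[r_auc.coef != 0].index)) and \
                   ({"x0", "x1"} <=
                    set(r_dev.coef[r_dev.coef != 0].index))
            agree += both
        assert agree >= 4


class TestInteractions:
    def test_two_retained_adds_one_column(self):
        task = _make_task()
        out = add_interactions(task, ["x0", "x1"])
        assert out.X.shape[1] == task.X.shape[1] + 1
        assert out.feature_names[-1] == "x0:x1"
        assert np.allclose(out.X[:, -1], task.X[:, 0] * task.X[:, 1])

    def test_true_interaction_detected(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(400 + seed)
            n = 800
            a = (rng.random(n) < 0.4).astype(float)
            b = (rng.random(n) < 0.4).astype(float)
            noise = rng.normal(0, 1, (n, 2))
            eta = -1.0 + 0.5 * a + 0.5 * b + 1.2 * a * b
            y = (rng.random(n) < expit(eta)).astype(float)
            task = LassoTask(
                X=np.column_stack([a, b, noise]), y=y, w=np.ones(n),
                feature_names=["a", "b", "n1", "n2"],
                patient_ids=np.arange(n).astype(str),
                modal_severe=y.astype(int))
            res = lasso.fit_with_interactions(task, ["a", "b"], n_folds=5,
                                              seed=seed)
            hits += res.coef.get("a:b", 0.0) != 0.0
        assert hits >= 4

    def test_fewer_than_two_retained_rejected(self):
        with pytest.raises(ValueError):
            add_interactions(_make_task(), ["x0"])


class TestPooling:
    def _result(self, coefs, names=("a", "b")):
        s = pd.Series(coefs, index=list(names))
        return LassoResult(lambda_path=np.array([0.1]), cv_curve=None,
                           selected_lambda=0.1, intercept=-1.0, coef=s,
                           odds_ratios=np.exp(s))

    def test_constant_coefficient_pools_to_its_or(self):
        results = [self._result([0.6, 0.0]) for _ in range(10)]
        pooled = pool_over_imputations(results)
        assert pooled.retained == ["a"]
        assert pooled.pooled_or["a"] == pytest.approx(np.exp(0.6))

    def test_minority_nonzero_not_retained(self):
        results = [self._result([0.5, 0.0]) if i < 4 else
                   self._result([0.0, 0.0]) for i in range(10)]
        pooled = pool_over_imputations(results)
        assert pooled.retained == []

    def test_mean_over_nonzero_imputations(self):
        results = [self._result([0.4, 0.0]) for _ in range(6)] + \
            [self._result([0.8, 0.0]) for _ in range(4)]
        pooled = pool_over_imputations(results)
        assert pooled.pooled_coef["a"] == pytest.approx(
            (0.4 * 6 + 0.8 * 4) / 10)

    def test_inconsistent_predictor_sets_rejected(self):
        with pytest.raises(ValueError):
            pool_over_imputations([self._result([0.1, 0.2]),
                                   self._result([0.1, 0.2], names=("a", "c"))])


class TestPredictionGrid:
    def _pooled(self, coef, intercept=0.0):
        from trajmix.lasso import PooledLasso
        s = pd.Series(coef)
        return PooledLasso(retained=list(s.index), pooled_coef=s,
                           pooled_or=np.exp(s), intercept=intercept,
                           per_imputation=[], retention_counts=s * 0)

    def test_null_model_gives_half(self):
        design = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 2.0]})
        pooled = self._pooled({}, intercept=0.0)
        combos = pd.DataFrame({"a": [0.0, 1.0]})
        out = predicted_probability_grid(pooled, combos, design)
        assert np.allclose(out["probability"], 0.5)

    def test_equal_or_binaries_coincide(self):
        design = pd.DataFrame({"a": [0, 1, 0, 1], "b": [0, 0, 1, 1],
                               "c": [2.0] * 4}, dtype=float)
        pooled = self._pooled({"a": 0.65, "b": 0.65}, intercept=-1.0)
        combos = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, dtype=float)
        out = predicted_probability_grid(pooled, combos, design)
        assert out["probability"].iloc[0] == pytest.approx(
            out["probability"].iloc[1])

    def test_monotone_in_negative_coefficient(self):
        design = pd.DataFrame({"das0": np.linspace(0, 5, 11)})
        pooled = self._pooled({"das0": -0.3}, intercept=0.5)
        combos = pd.DataFrame({"das0": np.linspace(0, 5, 11)})
        out = predicted_probability_grid(pooled, combos, design)
        assert (np.diff(out["probability"]) < 0).all()

    def test_unknown_covariate_rejected(self):
        design = pd.DataFrame({"a": [0.0, 1.0]})
        pooled = self._pooled({"a": 1.0})
        with pytest.raises(KeyError):
            predicted_probability_grid(
                pooled, pd.DataFrame({"zzz": [1.0]}), design)
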