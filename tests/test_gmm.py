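import numpy as np
import pandas as pd
import pytest

from trajmix import gmm, simulate
from trajmix.cohort import Cohort, truncate_followup
from trajmix.gmm import GMMParams, GMMSpec

from _oracles import patient_density_dense, patient_density_gh


def _one_patient_cohort(times, pga, centre="Other"):
    baseline = pd.DataFrame({
        "patient_id": ["p"], "sex": ["F"], "ethnicity": ["white"],
        "diagnosis": ["definite_jdm"], "centre": [centre],
        "age_at_diagnosis": [7.0], "time_to_first_visit": [times[0]],
        "pga0": [pga[0]], "cmas0": [40.0], "das0": [1.0],
        "arthritis": [0.0], "abnormal_respiration": [0.0],
        "calcinosis": [0.0], "lipodystrophy": [0.0], "ulceration": [0.0],
    })
    visits = pd.DataFrame({
        "patient_id": "p", "t": times, "pga": pga, "das": np.nan,
        "gottron": np.nan, "heliotrope": np.nan, "vasculitis": np.nan,
        "erythema": np.nan,
    })
    return Cohort(baseline=baseline, visits=visits)


def _toy_params(G=2, degree=3, q=2, gamma=(0.1,), seed=0):
    rng = np.random.default_rng(seed)
    L = np.array([[0.3, 0.0], [-0.05, 0.1]])[:q, :q]
    return GMMParams(
        theta=rng.normal(0, 0.5, G - 1),
        beta=rng.normal(0.8, 0.4, (G, degree + 1)) * [1, 0.3, 0.05, 0.01][:degree + 1],
        gamma=np.asarray(gamma, float),
        chol_D=L,
        log_sigma=np.log(0.4),
    )


class TestMarginalLoglik:
    def test_single_visit_standard_normal(self):
        """One visit, D=0, sigma=1, mean equal to the observation."""
        coh = _one_patient_cohort([0.0], [4.0])
        spec = GMMSpec(n_classes=1, time_degree=1, transform="sqrt",
                       random_effects="intercept", covariates=())
        params = GMMParams(
            theta=np.zeros(0), beta=np.array([[2.0, 0.0]]),
            gamma=np.zeros(0), chol_D=np.zeros((1, 1)), log_sigma=0.0)
        ll = gmm.marginal_loglik(params, coh, spec)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_degenerate_mixture_equals_single_class(self):
        coh = _one_patient_cohort([0.2, 1.0, 2.0, 4.0], [4.0, 2.2, 1.4, 1.1])
        spec2 = GMMSpec(n_classes=2, time_degree=2, covariates=())
        p2 = _toy_params(G=2, degree=2, gamma=())
        p2.theta = np.array([60.0])     # pi ~ (1, 0)
        spec1 = GMMSpec(n_classes=1, time_degree=2, covariates=())
        p1 = GMMParams(theta=np.zeros(0), beta=p2.beta[:1].copy(),
                       gamma=np.zeros(0), chol_D=p2.chol_D.copy(),
                       log_sigma=p2.log_sigma)
        assert gmm.marginal_loglik(p2, coh, spec2) == pytest.approx(
            gmm.marginal_loglik(p1, coh, spec1), abs=1e-8)

    def test_matches_gauss_hermite_oracle(self):
        """3 patients x 4 visits vs quadrature over the random effects."""
        rng = np.random.default_rng(3)
        params = _toy_params(G=2, degree=3, gamma=(0.1,), seed=1)
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        expected = 0.0
        cohorts = []
        for i, centre in enumerate(["A", "Other", "A"]):
            t = np.sort(rng.uniform(0.1, 6.0, 4))
            y = np.clip(rng.normal(1.5, 0.5, 4), 0.2, None) ** 2
            coh = _one_patient_cohort(t, y, centre=centre)
            cohorts.append(coh)
            expected += np.log(patient_density_gh(
                np.sqrt(y), t, float(centre == "A"), params))
        baseline = pd.concat([c.baseline for c in cohorts])
        baseline["patient_id"] = ["p0", "p1", "p2"]
        visits = pd.concat([
            c.visits.assign(patient_id=f"p{i}")
            for i, c in enumerate(cohorts)])
        merged = Cohort(baseline=baseline.reset_index(drop=True),
                        visits=visits.reset_index(drop=True))
        ll = gmm.marginal_loglik(params, merged, spec)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self,
                                                          sim_cohort_small):
        coh, _, _ = sim_cohort_small
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        data = gmm.prepare_data(coh, spec)
        rng = np.random.default_rng(0)
        x0 = gmm._single_class_start(data, spec, rng) \
            + rng.normal(0, 0.1, spec.n_params())
        _, grad = gmm._loglik_and_grad(x0, data, spec)
        for j in rng.choice(len(x0), size=6, replace=False):
            e = np.zeros_like(x0)
            e[j] = 1e-6
            num = (gmm._loglik_and_grad(x0 + e, data, spec)[0]
                   - gmm._loglik_and_grad(x0 - e, data, spec)[0]) / 2e-6
            assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-6)


class TestPosterior:
    def test_identical_classes_return_prior(self):
        coh = _one_patient_cohort([0.2, 1.0, 3.0], [4.0, 2.2, 1.4])
        spec = GMMSpec(n_classes=2, time_degree=1, covariates=())
        p = _toy_params(G=2, degree=1, gamma=())
        p.beta[1] = p.beta[0]
        p.theta = np.array([np.log(0.7 / 0.3)])
        post = gmm.posterior_probs(p, coh, spec)
        assert np.allclose(post.to_numpy()[0], [0.7, 0.3], atol=1e-12)

    def test_matches_independent_bayes_computation(self):
        rng = np.random.default_rng(5)
        spec = GMMSpec(n_classes=3, time_degree=2, covariates=("centre",))
        p = _toy_params(G=3, degree=2, gamma=(0.2,), seed=2)
        t = np.sort(rng.uniform(0.1, 8.0, 5))
        y = np.clip(rng.normal(1.4, 0.5, 5), 0.2, None) ** 2
        coh = _one_patient_cohort(t, y, centre="A")
        post = gmm.posterior_probs(p, coh, spec).to_numpy()[0]
        # direct Bayes rule with scipy densities, dense covariance
        dens = []
        for g in range(3):
            single = GMMParams(
                theta=np.zeros(0), beta=p.beta[[g]], gamma=p.gamma,
                chol_D=p.chol_D, log_sigma=p.log_sigma)
            dens.append(patient_density_dense(np.sqrt(y), t, 1.0, single,
                                              degree=2))
        pis = p.class_probs
        expected = pis * np.array(dens)
        expected /= expected.sum()
        assert np.allclose(post, expected, atol=1e-10)

    def test_rows_sum_to_one(self, sim_cohort_small):
        coh, _, spec = sim_cohort_small
        gspec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        p = _toy_params(G=2, degree=3, gamma=(0.1,))
        post = gmm.posterior_probs(p, coh, gspec)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestEntropyAndSummaries:
    def test_one_hot_entropy_is_one(self):
        P = np.eye(4)[np.array([0, 1, 2, 3, 0, 1])]
        assert gmm.entropy(P) == pytest.approx(1.0)

    def test_uniform_entropy_is_zero(self):
        P = np.full((7, 3), 1 / 3)
        assert gmm.entropy(P) == pytest.approx(0.0, abs=1e-12)

    def test_two_row_worked_example(self):
        P = np.array([[0.9, 0.1], [0.6, 0.4]])
        assert gmm.entropy(P) == pytest.approx(0.2800, abs=5e-4)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            gmm.entropy(np.ones((3, 1)))

    def test_mean_posterior_by_class(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7]])
        out = gmm.mean_posterior_by_class(P, [1, 1, 2])
        assert out == pytest.approx([0.85, 0.7])

    def test_mean_posterior_one_hot(self):
        P = np.eye(2)[[0, 1, 0]]
        assert gmm.mean_posterior_by_class(P, [1, 2, 1]) == pytest.approx(
            [1.0, 1.0])

    def test_mean_posterior_empty_class_is_nan(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2]])
        out = gmm.mean_posterior_by_class(P, [1, 1])
        assert out[0] == pytest.approx(0.85) and np.isnan(out[1])

    def test_bic_identity(self):
        assert gmm.bic(-100.0, 7, 50) == pytest.approx(
            200.0 + 7 * np.log(50), abs=1e-12)


class TestFit:
    def test_label_permutation_invariance(self, sim_cohort_small):
        coh, _, _ = sim_cohort_small
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        p = _toy_params(G=2, degree=3, gamma=(0.1,))
        pi = p.class_probs
        swapped = GMMParams(
            theta=np.array([np.log(pi[1] / pi[0])]),
            beta=p.beta[::-1].copy(), gamma=p.gamma, chol_D=p.chol_D,
            log_sigma=p.log_sigma)
        assert gmm.marginal_loglik(p, coh, spec) == pytest.approx(
            gmm.marginal_loglik(swapped, coh, spec), abs=1e-8)

    def test_canonical_order_descending_pi(self, sim_cohort_small):
        coh, _, _ = sim_cohort_small
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        fit = gmm.fit_gmm(coh, spec, n_starts=2, seed=0, max_iter=200)
        pi = fit.params.class_probs
        assert np.all(np.diff(pi) <= 0)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(fit.n_patients), abs=1e-9)
        assert np.allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        modal = fit.posterior.to_numpy().argmax(1) + 1
        assert (modal == fit.modal_class.to_numpy()).all()

    def test_iteration_cap_records_nonconvergence(self, sim_cohort_small):
        coh, _, _ = sim_cohort_small
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        fit = gmm.fit_gmm(coh, spec, n_starts=1, seed=0, max_iter=1)
        assert np.isfinite(fit.loglik)
        assert fit.convergence["converged"] is False

    def test_too_few_patients_raises(self, tiny_cohort):
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        with pytest.raises(ValueError, match="parameters"):
            gmm.fit_gmm(tiny_cohort, spec)

    def test_missing_outcome_patients_counted(self, tiny_cohort):
        visits = tiny_cohort.visits.copy()
        visits.loc[visits["patient_id"] == "b", "pga"] = np.nan
        coh = Cohort(baseline=tiny_cohort.baseline, visits=visits)
        spec = GMMSpec(n_classes=1, time_degree=1,
                       random_effects="intercept", covariates=())
        data = gmm.prepare_data(coh, spec)
        assert data.n_dropped == 1
        assert data.patient_ids == ["a"]


class TestPredictTrajectory:
    def _fitted(self, sim_cohort_small):
        coh, _, _ = sim_cohort_small
        spec = GMMSpec(n_classes=2, time_degree=3, covariates=("centre",))
        return coh, gmm.fit_gmm(coh, spec, n_starts=2, seed=0, max_iter=200)

    def test_sqrt_back_transform(self, sim_cohort_small):
        coh, fit = self._fitted(sim_cohort_small)
        grid = np.array([0.0, 1.0, 5.0])
        out = gmm.predict_trajectory(fit, 1, grid, coh, centre=0.0,
                                     ci="delta")
        eta = np.column_stack([grid ** k for k in range(4)]) \
            @ fit.params.beta[0]
        assert np.allclose(out["median"], np.clip(eta, 0, None) ** 2,
                           atol=1e-10)
        assert (out["lower"] <= out["median"]).all()
        assert (out["median"] <= out["upper"]).all()

    def test_extrapolation_flagged(self, sim_cohort_small):
        coh, fit = self._fitted(sim_cohort_small)
        out = gmm.predict_trajectory(fit, 1, [1.0, 50.0], coh, ci="delta")
        assert list(out["extrapolated"]) == [False, True]
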