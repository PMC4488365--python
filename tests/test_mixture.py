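import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import trajmix as tm
from trajmix.covariance import CovarianceModel
from trajmix.mixture import MixtureModel, pack_params, unpack_params
from trajmix.simulate import SimulationScenario, _shape_from_anchors
from trajmix.transform import CenteredPanel

from _oracles import direct_mixture_maximum, match_accuracy, tiny_two_group_scenario


def _toy_basis():
    return tm.build_spline_basis(np.repeat([2.0, 5.0, 9.0], 2))


def _flat_model(means, sigma2=1.0, gamma=None, K=None):
    """Model whose group mean curves are the constants ``means`` (partition
    of unity makes constant coefficient vectors constant curves)."""
    K = K or len(means)
    basis = _toy_basis()
    beta = np.array([[m] * basis.dimension for m in means], dtype=float)
    if gamma is None:
        gamma = np.zeros((K - 1, 1))
    return MixtureModel(
        K=K,
        beta=beta,
        cov=tuple(CovarianceModel("independence", sigma2) for _ in range(K)),
        gamma=np.asarray(gamma, dtype=float),
        basis=basis,
    )


def _centered_from_rows(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "age", "value"])
    means = pd.Series(0.0, index=df["subject_id"].unique())
    return CenteredPanel(df.sort_values(["subject_id", "age"]).reset_index(drop=True), means, ())


class TestMixtureLoglik:
    def test_single_component_matches_direct_mvn_density(self, small_centered):
        fit = tm.fit_em(small_centered, K=1, cov_kind="exponential", seed=0)
        model = fit.model
        total = 0.0
        for _, ages, values in small_centered.iter_subjects():
            mu = model.basis.design(ages) @ model.beta[0]
            Sigma = tm.covariance_matrix(model.cov[0], ages)
            total += multivariate_normal.logpdf(values, mean=mu, cov=Sigma)
        assert tm.mixture_loglik(model, small_centered) == pytest.approx(total, rel=1e-10)
        assert fit.loglik == pytest.approx(total, rel=1e-10)

    def test_degenerate_weight_limit_reduces_to_one_component(self):
        rows = [(f"S{i}", a, v) for i in range(6) for a, v in zip((2, 5, 9), (-1.0, 0.5, 0.5))]
        cp = _centered_from_rows(rows)
        two = _flat_model([0.0, 3.0], gamma=[[30.0]])
        one = _flat_model([0.0], K=1)
        assert tm.mixture_loglik(two, cp) == pytest.approx(
            tm.mixture_loglik(one, cp), abs=1e-8
        )

    def test_two_identical_subjects_contribute_twice_one_term(self):
        base = [(2.0, -1.2), (5.0, 0.4), (9.0, 0.8)]
        one = _centered_from_rows([("A", a, v) for a, v in base])
        two = _centered_from_rows(
            [("A", a, v) for a, v in base] + [("B", a, v) for a, v in base]
        )
        model = _flat_model([0.0, 1.0])
        assert tm.mixture_loglik(model, two) == pytest.approx(
            2.0 * tm.mixture_loglik(model, one), rel=1e-12
        )


class TestEStep:
    def test_identical_components_give_half(self):
        cp = _centered_from_rows([("A", 5.0, 0.7)])
        post = tm.e_step(_flat_model([0.3, 0.3]), cp)
        np.testing.assert_allclose(post.to_numpy(), [[0.5, 0.5]], atol=1e-12)

    def test_single_component_posterior_is_one(self, small_centered):
        fit = tm.fit_em(small_centered, K=1, seed=0)
        post = tm.e_step(fit.model, small_centered)
        np.testing.assert_allclose(post.to_numpy(), 1.0, atol=0)

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.3, 2.5])
    def test_two_component_posterior_matches_bayes_rule(self, y):
        # independent hand computation: components N(-1, 1) and N(+1, 1)
        cp = _centered_from_rows([("A", 5.0, y)])
        post = tm.e_step(_flat_model([-1.0, 1.0]), cp)
        expected = norm.pdf(y, 1.0, 1.0) / (norm.pdf(y, -1.0, 1.0) + norm.pdf(y, 1.0, 1.0))
        assert post.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one_and_nonnegative(self, small_centered, small_fit_k2):
        post = tm.e_step(small_fit_k2.model, small_centered).to_numpy()
        assert np.all(post >= 0)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStepMeans:
    def test_hard_posteriors_independence_equals_group_ols(self, small_centered):
        prep_rows = list(small_centered.iter_subjects())
        n = len(prep_rows)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=n)
        W = np.zeros((n, 2))
        W[np.arange(n), labels] = 1.0
        basis = tm.build_spline_basis(
            np.concatenate([ages for _, ages, _ in prep_rows])
        )
        beta = tm.m_step_means(W, small_centered, basis)
        # subjects iterate in the same sorted order as the posterior rows
        for g in range(2):
            X = np.vstack([basis.design(a) for (_, a, _), l in zip(prep_rows, labels) if l == g])
            y = np.concatenate([v for (_, _, v), l in zip(prep_rows, labels) if l == g])
            expected, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(beta[g], expected, atol=1e-8)

    def test_k1_exponential_equals_direct_gls(self, small_centered):
        fit = tm.fit_em(small_centered, K=1, cov_kind="exponential", seed=0)
        cov = fit.model.cov[0]
        basis = fit.model.basis
        A = np.zeros((4, 4))
        b = np.zeros(4)
        for _, ages, values in small_centered.iter_subjects():
            X = basis.design(ages)
            Sinv = np.linalg.inv(tm.covariance_matrix(cov, ages))
            A += X.T @ Sinv @ X
            b += X.T @ Sinv @ values
        # beta is the GLS solution at the covariance of the penultimate
        # EM iteration; agreement is up to the convergence tolerance
        np.testing.assert_allclose(fit.model.beta[0], np.linalg.solve(A, b), atol=1e-4)

    def test_zero_response_gives_zero_coefficients(self):
        rows = [(f"S{i}", a, 0.0) for i in range(8) for a in (2, 3.5, 5, 7, 9)]
        cp = _centered_from_rows(rows)
        basis = tm.build_spline_basis(np.tile([2, 3.5, 5, 7, 9], 8))
        beta = tm.m_step_means(np.ones((8, 1)), cp, basis)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)


class TestMStepCovariance:
    def test_hard_residuals_mean_square(self):
        rows = [("A", a, v) for a, v in zip((2, 3.5, 5, 7), (1.0, -1.0, 1.0, -1.0))]
        cp = _centered_from_rows(rows)
        basis = _toy_basis()
        (cov,) = tm.m_step_covariance(np.ones((1, 1)), cp, basis, np.zeros((1, 4)))
        assert cov.sigma2 == pytest.approx(1.0)

    def test_exponential_phi_recovery_within_15_percent(self):
        true = CovarianceModel("exponential", 1.0, 2.0)
        ages = np.array([2.0, 3.5, 5.0, 7.0, 9.0])
        Sigma = tm.covariance_matrix(true, ages)
        rng = np.random.default_rng(12)
        Y = rng.multivariate_normal(np.zeros(5), Sigma, size=1000)
        rows = [(f"S{i:04d}", a, v) for i, row in enumerate(Y) for a, v in zip(ages, row)]
        cp = _centered_from_rows(rows)
        basis = tm.build_spline_basis(np.tile(ages, 4))
        (cov,) = tm.m_step_covariance(
            np.ones((1000, 1)), cp, basis, np.zeros((1, 4)), kind="exponential"
        )
        assert abs(cov.phi - true.phi) / true.phi < 0.15
        assert abs(cov.sigma2 - true.sigma2) / true.sigma2 < 0.15

    def test_zero_residuals_hit_floor_with_warning(self):
        rows = [("A", a, 0.0) for a in (2, 3.5, 5, 7)]
        cp = _centered_from_rows(rows)
        with pytest.warns(UserWarning, match="floor"):
            (cov,) = tm.m_step_covariance(np.ones((1, 1)), cp, _toy_basis(), np.zeros((1, 4)))
        assert cov.sigma2 == pytest.approx(1e-8)


class TestMStepConcomitant:
    def test_intercept_only_uniform_posteriors_give_zero(self):
        W = np.full((40, 4), 0.25)
        gamma = tm.m_step_concomitant(W, np.ones((40, 1)))
        np.testing.assert_allclose(gamma, 0.0, atol=1e-12)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(4)
        W = rng.dirichlet([2.0, 1.0, 3.0], size=200)
        gamma = tm.m_step_concomitant(W, np.ones((200, 1)))
        means = W.mean(axis=0)
        np.testing.assert_allclose(
            gamma.ravel(), np.log(means[:2] / means[2]), atol=1e-12
        )

    def test_hard_labels_match_statsmodels_mnlogit(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        eta = np.column_stack([0.5 + 1.0 * x, np.zeros(n)])
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        lab = np.array([rng.choice(2, p=pi) for pi in p])  # 0 = group 1, 1 = reference
        W = np.zeros((n, 2))
        W[np.arange(n), lab] = 1.0
        Z = np.column_stack([np.ones(n), x])
        gamma = tm.m_step_concomitant(W, Z)
        # statsmodels codes the first category (0) as reference; relabel so
        # our reference group (last) is statsmodels' category 0
        endog = 1 - lab
        fitted = sm.MNLogit(endog, Z).fit(disp=0)
        np.testing.assert_allclose(gamma.ravel(), fitted.params.ravel(), atol=1e-4)

    def test_separation_yields_bounded_log_odds(self):
        # perfectly separated hard labels: the MLE is at infinity, but the
        # update must return finite coefficients with |log-odds| <= 30
        x = np.concatenate([np.full(20, -3.0), np.full(20, 3.0)])
        W = np.zeros((40, 2))
        W[:20, 0] = 1.0
        W[20:, 1] = 1.0
        Z = np.column_stack([np.ones(40), x])
        gamma = tm.m_step_concomitant(W, Z)
        assert np.all(np.isfinite(gamma))
        assert np.max(np.abs(Z @ gamma.T)) <= 30.0 + 1e-9


class TestFitEM:
    def test_k1_is_a_single_gls_fit(self, small_centered):
        fit = tm.fit_em(small_centered, K=1, seed=0)
        assert fit.n_iter <= 2
        np.testing.assert_allclose(fit.posteriors, 1.0)
        assert fit.converged

    def test_well_separated_two_groups_recovered(self):
        sc = replace(
            tiny_two_group_scenario(seed=1, n_subjects=200),
            noise=CovarianceModel("independence", 0.09),
        )
        cohort = tm.simulate_cohort(sc)
        centered = tm.center_trajectories(cohort.panel)
        fit = tm.fit_em(centered, K=2, seed=3, n_starts=6)
        acc = match_accuracy(fit.labels, cohort.true_label_array())
        assert acc >= 0.99

    def test_em_attains_direct_numerical_maximum(self):
        cohort = tm.simulate_cohort(tiny_two_group_scenario(seed=2))
        centered = tm.center_trajectories(cohort.panel)
        fit = tm.fit_em(centered, K=2, seed=5, n_starts=8)
        direct = direct_mixture_maximum(centered, seed=99)
        assert fit.loglik >= direct - 1e-4

    def test_trace_monotone_and_labels_ordered(self, small_centered):
        fit = tm.fit_em(small_centered, K=3, seed=9, n_starts=4)
        assert np.all(np.diff(fit.trace) >= -1e-8 * (np.abs(fit.trace[:-1]) + 1))
        curves = fit.model.mean_curves([9.0]).ravel()
        assert np.all(np.diff(curves) <= 1e-12)  # group 1 highest at age 9

    def test_subject_order_invariance(self, small_cohort):
        records = small_cohort.panel.records
        shuffled = tm.TrajectoryPanel(records.sample(frac=1.0, random_state=1))
        a = tm.fit_em(tm.center_trajectories(small_cohort.panel), K=2, seed=4, n_starts=3)
        b = tm.fit_em(tm.center_trajectories(shuffled), K=2, seed=4, n_starts=3)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.posteriors, b.posteriors)


class TestBicAndSelection:
    def test_bic_formula(self, small_fit_k2):
        fit = small_fit_k2
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * math.log(fit.n_subjects)
        )

    def test_parameter_count_exponential_no_covariates(self):
        model = MixtureModel(
            K=4,
            beta=np.zeros((4, 4)),
            cov=tuple(CovarianceModel("exponential", 1.0, 1.0) for _ in range(4)),
            gamma=np.zeros((3, 1)),
            basis=_toy_basis(),
        )
        assert model.n_params == 16 + 8 + 3

    def test_selection_table_has_one_row_per_cell(self, small_centered):
        best, table = tm.select_model(
            small_centered, K_range=(1, 2), cov_kinds=("independence", "exponential"),
            seed=3, n_starts=2,
        )
        assert len(table) == 4
        assert set(table["K"]) == {1, 2}
        assert best.bic == table["bic"].min()


class TestClassify:
    def _fake_fit(self, posteriors):
        W = np.asarray(posteriors, dtype=float)
        n, K = W.shape
        model = _flat_model(list(range(K)), K=K)
        return tm.FitResult(
            model=model, loglik=0.0, bic=0.0, n_subjects=n, n_params=model.n_params,
            posteriors=W, subject_ids=[f"S{i}" for i in range(n)],
            labels=np.argmax(W, axis=1) + 1, converged=True, n_iter=1,
            trace=np.zeros(1),
        )

    def test_max_posterior_and_tie_rule(self):
        labels, _ = tm.classify(self._fake_fit([[0.6, 0.4], [0.5, 0.5], [0.2, 0.8]]))
        assert labels.tolist() == [1, 1, 2]

    def test_uncertainty_fraction(self):
        _, unc = tm.classify(self._fake_fit([[0.95, 0.05], [0.5, 0.5]]))
        assert unc["frac_uncertain"].tolist() == [0.5, 0.5]
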