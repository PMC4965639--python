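"""Logistic IRLS and closed-form LDA, checked against independent oracles
(closed forms, grid search, statsmodels, scikit-learn, Gaussian densities)."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal

import discrimbench as db
from discrimbench.classifiers import FitError, SeparationWarning


def make_cohort(y, **columns):
    schema = tuple(
        db.Predictor(name, "binary" if set(np.unique(v)) <= {0, 1} else "continuous")
        for name, v in columns.items()
    )
    return db.Cohort(schema=schema, data=pd.DataFrame({"outcome": y, **columns}))


def two_by_two_cohort():
    """Cell counts (y=1,x=1)=20, (y=1,x=0)=10, (y=0,x=1)=10, (y=0,x=0)=20."""
    y = np.array([1] * 30 + [0] * 30)
    x = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
    return make_cohort(y, exposure=x)


def grid_search_mle(y, x, span=4.0, points=81, zooms=6):
    """Coarse-to-fine grid maximization of the Bernoulli likelihood."""
    b0, b1, width = 0.0, 0.0, span
    for _ in range(zooms):
        g0 = np.linspace(b0 - width, b0 + width, points)
        g1 = np.linspace(b1 - width, b1 + width, points)
        ll = np.empty((points, points))
        for i, a in enumerate(g0):
            eta = a + np.outer(g1, x)
            ll[:, i] = -np.logaddexp(0, -(2 * y - 1) * eta).sum(axis=1)
        j, i = np.unravel_index(np.argmax(ll), ll.shape)
        b0, b1 = g0[i], g1[j]
        width /= 10
    return b0, b1


class TestLogistic:
    def test_null_predictor_coefficient_near_zero(self, rng):
        y = rng.integers(0, 2, 10_000)
        x = rng.integers(0, 2, 10_000)  # independent of y
        model = db.fit_logistic(make_cohort(y, noise=x))
        assert abs(model.coefficients["noise"]) < 0.1
        assert model.converged

    def test_two_by_two_slope_is_log_four(self):
        cohort = two_by_two_cohort()
        model = db.fit_logistic(cohort)
        assert model.coefficients["exposure"] == pytest.approx(np.log(4), abs=1e-6)
        # cross-check against the grid-search likelihood oracle
        b0, b1 = grid_search_mle(cohort.outcome,
                                 cohort.data["exposure"].to_numpy(float))
        assert model.coefficients["exposure"] == pytest.approx(b1, abs=1e-4)
        assert model.intercept == pytest.approx(b0, abs=1e-4)

    def test_parameter_recovery_within_three_se(self, big_logistic_cohort):
        cfg = db.paper_like()
        model = db.fit_logistic(big_logistic_cohort)
        truth = {"(intercept)": cfg.intercept, **cfg.coefficients}
        for name, true_beta in truth.items():
            est = model.intercept if name == "(intercept)" else model.coefficients[name]
            assert abs(est - true_beta) < 3 * model.standard_errors[name]

    def test_agrees_with_statsmodels(self, paper_cohort):
        sm = pytest.importorskip("statsmodels.api")
        X, names, _ = db.design_matrix(paper_cohort)
        res = sm.Logit(paper_cohort.outcome, sm.add_constant(X)).fit(disp=0)
        model = db.fit_logistic(paper_cohort)
        assert model.intercept == pytest.approx(res.params[0], abs=1e-6)
        for j, name in enumerate(names):
            assert model.coefficients[name] == pytest.approx(res.params[j + 1], abs=1e-6)
            assert model.standard_errors[name] == pytest.approx(res.bse[j + 1], rel=1e-4)
        assert model.log_likelihood == pytest.approx(res.llf, abs=1e-8)

    def test_loglik_nondecreasing_over_irls(self, paper_cohort):
        path = np.array(db.fit_logistic(paper_cohort).loglik_path)
        assert (np.diff(path) >= -1e-9).all()

    def test_separation_flagged_not_fatal(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.array([0.0] * 20 + [1.0] * 20)  # perfect separation
        with pytest.warns(SeparationWarning):
            model = db.fit_logistic(make_cohort(y, split=x))
        assert not model.converged
        pred = db.predict_logistic(model, make_cohort(y, split=x))
        assert np.isfinite(pred.probabilities).all()
        assert (pred.labels == y).all()

    def test_degenerate_designs_rejected(self, rng):
        y = rng.integers(0, 2, 50)
        x = rng.normal(size=50)
        with pytest.raises(FitError, match="single class"):
            db.fit_logistic(make_cohort(np.ones(50, dtype=int), x=x))
        with pytest.raises(FitError, match="rank-deficient"):
            db.fit_logistic(make_cohort(y, x=x, x2=2 * x))


class TestPredictLogistic:
    def test_flat_model_predicts_half(self, paper_cohort):
        model = db.fit_logistic(paper_cohort)
        flat = db.LogisticModel(
            intercept=0.0,
            coefficients={k: 0.0 for k in model.coefficients},
            converged=True, n_iterations=1, log_likelihood=0.0,
            standard_errors=model.standard_errors, loglik_path=(0.0,),
            design_columns=model.design_columns, column_source=model.column_source,
        )
        pred = db.predict_logistic(flat, paper_cohort)
        assert (pred.probabilities == 0.5).all()
        assert (pred.labels == 1).all()  # tie at 0.5 goes to group 1

    def test_saturated_intercept(self, paper_cohort):
        model = db.fit_logistic(paper_cohort)
        sat = db.LogisticModel(
            intercept=30.0,
            coefficients={k: 0.0 for k in model.coefficients},
            converged=True, n_iterations=1, log_likelihood=0.0,
            standard_errors=model.standard_errors, loglik_path=(0.0,),
            design_columns=model.design_columns, column_source=model.column_source,
        )
        pred = db.predict_logistic(sat, paper_cohort)
        assert (pred.probabilities >= 1 - 1e-9).all()
        assert (pred.labels == 1).all()

    def test_hand_evaluated_link(self):
        y = np.array([1, 0])
        x = np.array([1.0, 0.0])
        hand = db.LogisticModel(
            intercept=-1.0, coefficients={"x": 2.0}, converged=True,
            n_iterations=1, log_likelihood=0.0, standard_errors={},
            loglik_path=(0.0,), design_columns=("x",),
            column_source={"x": "x"},
        )
        pred = db.predict_logistic(hand, make_cohort(y, x=x))
        assert pred.probabilities[0] == pytest.approx(expit(1.0), abs=1e-12)

    def test_column_mismatch_rejected(self, paper_cohort, rng):
        model = db.fit_logistic(paper_cohort)
        other = make_cohort(rng.integers(0, 2, 10), weird=rng.normal(size=10))
        with pytest.raises(FitError, match="match"):
            db.predict_logistic(model, other)


class TestLDA:
    def test_identical_means_leave_priors_in_charge(self, rng):
        y = rng.integers(0, 2, 20_000)
        x = rng.normal(size=20_000)  # same distribution in both classes
        model = db.fit_lda(make_cohort(y, x=x))
        assert abs(model.group_weights[1][0] - model.group_weights[0][0]) < 0.1

    def test_one_dimensional_closed_form(self):
        # deterministic fixture; independent pooled-variance computation
        y = np.array([0] * 5 + [1] * 5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        model = db.fit_lda(make_cohort(y, x=x))
        m0, m1 = x[:5].mean(), x[5:].mean()
        s2 = (((x[:5] - m0) ** 2).sum() + ((x[5:] - m1) ** 2).sum()) / (10 - 2)
        expected = (m1 - m0) / s2
        got = model.group_weights[1][0] - model.group_weights[0][0]
        assert got == pytest.approx(expected, abs=1e-8)

    def test_pooled_covariance_recovery(self, rng):
        cohort = db.generate_cohort(db.lda_paper_like(seed=4, n=50_000))
        cont = cohort.with_predictors(["duration"])
        model = db.fit_lda(cont)
        assert np.linalg.norm(model.pooled_covariance - np.array([[2.0]])) < 0.05

    def test_singular_covariance_named(self, rng):
        y = rng.integers(0, 2, 40)
        x = rng.normal(size=40)
        with pytest.raises(FitError, match="singular"):
            db.fit_lda(make_cohort(y, x=x, x2=2 * x))

    def test_agrees_with_sklearn(self, big_lda_cohort):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        X, _, _ = db.design_matrix(big_lda_cohort)
        y = big_lda_cohort.outcome
        ref = sk.LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        model = db.fit_lda(big_lda_cohort)
        pred = db.predict_lda(model, big_lda_cohort)
        assert (pred.labels == ref.predict(X)).mean() > 0.999
        assert np.abs(pred.probabilities - ref.predict_proba(X)[:, 1]).max() < 0.01


class TestScoresAndPosterior:
    def test_midpoint_record_scores_equal(self):
        y = np.array([0] * 4 + [1] * 4)
        x = np.array([0.0, 1.0, 2.0, 1.0, 4.0, 5.0, 6.0, 5.0])
        model = db.fit_lda(make_cohort(y, x=x), equal_priors=True)
        mid = make_cohort(np.array([0, 1]), x=np.full(2, x.mean()))
        z0, z1 = db.lda_scores(model, mid)
        assert z0 == pytest.approx(z1, abs=1e-10)
        assert db.predict_lda(model, mid).probabilities == pytest.approx(0.5, abs=1e-12)

    def test_own_mean_dominates_with_equal_priors(self, big_lda_cohort):
        model = db.fit_lda(big_lda_cohort, equal_priors=True)
        names = list(model.design_columns)
        at_mu1 = db.Cohort(
            schema=tuple(db.Predictor(n, "continuous") for n in names),
            data=pd.DataFrame(
                {"outcome": [1], **{n: [model.group_means[1][j]]
                                    for j, n in enumerate(names)}}
            ),
        )
        z0, z1 = db.lda_scores(model, at_mu1)
        assert z1[0] > z0[0]

    def test_score_difference_equals_affine_discriminant(self, big_lda_cohort, rng):
        model = db.fit_lda(big_lda_cohort)
        sub = big_lda_cohort.take(rng.choice(big_lda_cohort.n, 500, replace=False))
        z0, z1 = db.lda_scores(model, sub)
        X, _, _ = db.design_matrix(sub)
        Si = np.linalg.inv(model.pooled_covariance)
        m0, m1 = model.group_means
        w = Si @ (m1 - m0)
        c = -0.5 * (m1 @ Si @ m1 - m0 @ Si @ m0) + np.log(
            model.priors[1] / model.priors[0]
        )
        np.testing.assert_allclose(z1 - z0, X @ w + c, atol=1e-10)

    def test_posterior_equals_gaussian_bayes_ratio(self, rng):
        """logit^{-1}(Z1-Z0) vs the direct density-ratio oracle, 1000 records."""
        cohort = db.generate_cohort(
            db.CohortConfig(
                regime="lda_gaussian", n=2_000, seed=9,
                class_means={0: {"a": 0.0, "b": 1.0}, 1: {"a": 1.0, "b": 2.0}},
                shared_covariance=((1.0, 0.3), (0.3, 2.0)),
                class_binary_probs={0: {}, 1: {}},
            )
        )
        model = db.fit_lda(cohort)
        sub = cohort.take(rng.choice(cohort.n, 1000, replace=False))
        X, _, _ = db.design_matrix(sub)
        f0 = multivariate_normal(model.group_means[0], model.pooled_covariance).pdf(X)
        f1 = multivariate_normal(model.group_means[1], model.pooled_covariance).pdf(X)
        bayes = model.priors[1] * f1 / (model.priors[0] * f0 + model.priors[1] * f1)
        np.testing.assert_allclose(
            db.predict_lda(model, sub).probabilities, bayes, atol=1e-10
        )

    def test_probability_rule_matches_highest_score_rule(self, big_lda_cohort):
        model = db.fit_lda(big_lda_cohort)
        pred = db.predict_lda(model, big_lda_cohort)
        z0, z1 = db.lda_scores(model, big_lda_cohort)
        assert (pred.labels == (z1 >= z0).astype(int)).all()
        assert ((pred.probabilities > 0) & (pred.probabilities < 1)).all()


class TestDummyCoding:
    def test_categorical_enters_as_k_minus_one_dummies(self, paper_cohort):
        cat = db.categorize_duration(paper_cohort, db.empirical_tertiles(paper_cohort))
        X, names, source = db.design_matrix(cat)
        assert names == ["family_history", "satisfaction", "duration[1]", "duration[2]"]
        assert source["duration[1]"] == "duration"
        lr = db.fit_logistic(cat)
        lda = db.fit_lda(cat)
        assert lr.design_columns == lda.design_columns  # identical treatment

    def test_asymptotic_boundary_agreement_on_gaussian_data(self, big_lda_cohort):
        lr = db.fit_logistic(big_lda_cohort)
        lda = db.fit_lda(big_lda_cohort)
        disagree = (
            db.predict_logistic(lr, big_lda_cohort).labels
            != db.predict_lda(lda, big_lda_cohort).labels
        ).mean()
        assert disagree < 0.01


class TestPersistence:
    def test_round_trip_both_model_types(self, paper_cohort, tmp_path):
        lr = db.fit_logistic(paper_cohort)
        lda = db.fit_lda(paper_cohort)
        db.save_model(lr, tmp_path / "lr.json")
        db.save_model(lda, tmp_path / "lda.json")
        lr2 = db.load_model(tmp_path / "lr.json")
        lda2 = db.load_model(tmp_path / "lda.json")
        p1 = db.predict_logistic(lr2, paper_cohort).probabilities
        np.testing.assert_array_equal(p1, db.predict_logistic(lr, paper_cohort).probabilities)
        p2 = db.predict_lda(lda2, paper_cohort).probabilities
        np.testing.assert_array_equal(p2, db.predict_lda(lda, paper_cohort).probabilities)
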