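"""OLS fitting, LOOCV scoring, VIF, likelihood-ratio tests, model search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from irae_screen import (
    ExhaustiveModelSearch,
    FactorMatrix,
    LinearRiskModel,
    enumerate_and_rank,
    fit_ols,
    loocv_r,
    lr_test,
    predict_external,
    unexplained_variance,
    vif,
)
from irae_screen.errors import InputError, NestingError, SingularDesignError
from irae_screen.models import ModelFit

from conftest import make_factor_matrix


def normal_equations(X, y):
    """Independent oracle: solve (D'D) beta = D'y directly."""
    D = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    beta = np.linalg.solve(D.T @ D, D.T @ np.asarray(y, dtype=float))
    return beta[0], beta[1:]


def explicit_loocv(X, y):
    """Independent oracle: refit every fold from scratch."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = np.empty(len(y))
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        D = np.column_stack([np.ones(mask.sum()), X[mask]])
        beta, *_ = np.linalg.lstsq(D, y[mask], rcond=None)
        preds[i] = np.concatenate([[1.0], X[i]]) @ beta
    return preds


class TestFitOLS:
    def test_normal_equations_oracle_five_points(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0, 4.0], "b": [1.0, 0.0, 2.0, 1.0, 3.0]})
        y = np.array([0.5, 1.7, 3.1, 3.9, 6.2])
        coef, intercept, rss, loglik = fit_ols(X, y)
        b0, b = normal_equations(X, y)
        assert intercept == pytest.approx(b0, abs=1e-10)
        assert coef["a"] == pytest.approx(b[0], abs=1e-10)
        assert coef["b"] == pytest.approx(b[1], abs=1e-10)
        resid = y - (b0 + X.to_numpy() @ b)
        assert rss == pytest.approx(resid @ resid, abs=1e-10)
        sigma2 = rss / len(y)
        assert loglik == pytest.approx(
            -0.5 * len(y) * (np.log(2 * np.pi * sigma2) + 1), abs=1e-10
        )

    def test_intercept_only_constant_outcome(self):
        _, intercept, rss, _ = fit_ols(pd.DataFrame(index=range(5)), np.full(5, 3.0))
        assert intercept == pytest.approx(3.0)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_perfect_fit_floored_and_flagged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        model = LinearRiskModel().fit(X, 2 * X["a"] + 1)
        assert model.degenerate_fit_
        assert np.isfinite(model.loglik_)

    def test_rank_deficiency_raises(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        X["b"] = 2 * X["a"]
        with pytest.raises(SingularDesignError):
            fit_ols(X, np.arange(5.0))


class TestLOOCV:
    def test_exact_linear_relation_gives_r_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=8)})
        r, p, _ = loocv_r(X, 3 * X["a"] - 2)
        assert r == pytest.approx(1.0)

    def test_matches_explicit_refit_loop(self, rng):
        for _ in range(10):
            n, p = int(rng.integers(6, 15)), int(rng.integers(1, 4))
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
            y = rng.normal(size=n)
            _, _, preds = loocv_r(X, y)
            assert np.allclose(preds, explicit_loocv(X, y), atol=1e-12)

    def test_pure_noise_mean_r_negative_never_optimistic(self):
        # Held-out predictions of an uninformative model anti-correlate with
        # the outcome (LOOCV pessimism), so the mean r is clearly below zero.
        rs = []
        gen = np.random.default_rng(5)
        for _ in range(200):
            X = pd.DataFrame({"a": gen.normal(size=10)})
            r, _, _ = loocv_r(X, gen.normal(size=10))
            rs.append(r)
        assert -0.7 < np.mean(rs) < 0.0

    def test_too_few_observations(self, rng):
        with pytest.raises(InputError):
            loocv_r(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), np.array([1.0, 2.0, 3.0]))


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        out = vif(X)
        assert out["a"] == pytest.approx(1.0, abs=1e-12)
        assert out["b"] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_predictor_infinite(self, rng):
        a = rng.normal(size=10)
        out = vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_near_collinear_exceeds_threshold_and_matches_oracle(self, rng):
        a = rng.normal(size=30)
        b = a + 0.05 * rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=30)})
        out = vif(X)
        for j, name in enumerate(X.columns):
            others = X.drop(columns=name).to_numpy()
            D = np.column_stack([np.ones(30), others])
            beta, *_ = np.linalg.lstsq(D, X[name].to_numpy(), rcond=None)
            resid = X[name].to_numpy() - D @ beta
            r2 = 1 - resid @ resid / np.sum((X[name] - X[name].mean()) ** 2)
            assert out[name] == pytest.approx(1 / (1 - r2), rel=1e-10)
        assert out["a"] > 4 and out["b"] > 4

    def test_needs_two_predictors(self):
        with pytest.raises(InputError):
            vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


def _fit_modelfit(X, y, predictors):
    coef, intercept, rss, loglik = fit_ols(X[list(predictors)], y)
    return ModelFit(
        predictors=tuple(predictors), coefficients=coef, intercept=intercept,
        rss=rss, loglik=loglik, n=len(y), loocv_r=np.nan, loocv_p=np.nan,
        unexplained_variance=np.nan,
    )


class TestLRTest:
    def test_zero_extra_coefficient_gives_lambda_zero(self, rng):
        # Build x2 orthogonal to 1, x1 and y: its OLS coefficient is exactly 0.
        n = 12
        x1 = rng.normal(size=n)
        y = 2 * x1 + rng.normal(size=n)
        x2 = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), x1, y])
        Q, _ = np.linalg.qr(basis)
        x2 = x2 - Q @ (Q.T @ x2)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        lam, p = lr_test(_fit_modelfit(X, y, ("x1", "x2")), _fit_modelfit(X, y, ("x1",)))
        assert lam == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_matches_independent_two_fit_computation(self, rng):
        X = pd.DataFrame(
            {"a": [0.1, 0.9, 2.2, 2.8, 4.1, 5.0], "b": [1.0, 0.0, 1.5, 0.5, 2.0, 1.0]}
        )
        y = np.array([0.3, 1.1, 2.0, 3.2, 4.1, 5.3])
        full = _fit_modelfit(X, y, ("a", "b"))
        reduced = _fit_modelfit(X, y, ("a",))
        lam, p = lr_test(full, reduced)

        def loglik(preds):
            D = np.column_stack([np.ones(6)] + [X[c].to_numpy() for c in preds])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            rss = np.sum((y - D @ beta) ** 2)
            return -0.5 * 6 * (np.log(2 * np.pi * rss / 6) + 1)

        assert lam == pytest.approx(2 * (loglik(("a", "b")) - loglik(("a",))), abs=1e-10)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(lam, 1), rel=1e-12)

    def test_lambda_nonnegative_on_random_nested_pairs(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 16))
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
            y = rng.normal(size=n)
            lam, _ = lr_test(
                _fit_modelfit(X, y, ("a", "b", "c")), _fit_modelfit(X, y, ("a",))
            )
            assert lam >= 0.0

    def test_non_nested_pair_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        y = rng.normal(size=8)
        with pytest.raises(NestingError):
            lr_test(_fit_modelfit(X, y, ("a",)), _fit_modelfit(X, y, ("b",)))


class TestEnumerateAndRank:
    def test_subset_counts_match_binomials(self, rng):
        fm = make_factor_matrix(rng, n_types=21, factors=tuple(f"f{i}" for i in range(12)))
        fits = enumerate_and_rank(fm, sizes=(2,))
        assert len(fits) == 66
        fm3 = make_factor_matrix(rng, n_types=10, factors=("a", "b", "c"))
        assert len(enumerate_and_rank(fm3, sizes=(3,))) == 1
        assert len(enumerate_and_rank(fm3, sizes=(1,))) == 3

    def test_planted_trivariate_truth_recovered(self, rng):
        # The printed trivariate combination used as a planted truth.
        beta = {"DC": 19.03, "TMB": 0.82, "naiveCD4T": 18.03}
        intercept = -1.85
        X = pd.DataFrame(
            {
                "DC": rng.uniform(0.03, 0.15, 21),
                "TMB": rng.uniform(1.2, 3.2, 21),
                "naiveCD4T": rng.uniform(0.03, 0.15, 21),
                "null": rng.normal(size=21),
            }
        )
        y = intercept + sum(beta[k] * X[k] for k in beta)
        fits = enumerate_and_rank(FactorMatrix(values=X, outcome=y), sizes=(3,))
        top = fits[0]
        assert top.predictors == ("DC", "TMB", "naiveCD4T")
        for k, v in beta.items():
            assert top.coefficients[k] == pytest.approx(v, abs=1e-6)
        assert top.intercept == pytest.approx(intercept, abs=1e-6)
        assert top.loocv_r >= 0.999

    def test_noise_predictor_never_increases_rss(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "noise"])
        y = rng.normal(size=12)
        full = _fit_modelfit(X, y, ("a", "noise"))
        reduced = _fit_modelfit(X, y, ("a",))
        assert full.rss <= reduced.rss + 1e-12

    def test_ranking_tie_break_is_deterministic(self, rng):
        fm = make_factor_matrix(rng, n_types=10, factors=("a", "b"))
        fm.values["b"] = fm.values["a"].copy()  # bit-identical LOOCV scores
        fits = enumerate_and_rank(fm, sizes=(1,))
        assert [m.predictors for m in fits] == [("a",), ("b",)]

    def test_insufficient_types_for_size(self, rng):
        fm = make_factor_matrix(rng, n_types=5, factors=("a", "b", "c"))
        with pytest.raises(InputError):
            enumerate_and_rank(fm, sizes=(3,))

    def test_admissibility_flags_collinear_model(self, rng):
        fm = make_factor_matrix(rng, n_types=15, factors=("a", "b"))
        fm.values["b"] = fm.values["a"] + 0.01 * rng.normal(size=15)
        fits = enumerate_and_rank(fm, sizes=(2,))
        assert not fits[0].admissible
        assert fits[0].vif_max > 4

    def test_search_estimator_sklearn_contract(self, rng):
        from sklearn.base import clone

        fm = make_factor_matrix(rng, n_types=12, factors=("a", "b", "c"))
        est = ExhaustiveModelSearch(sizes=(1, 2))
        cloned = clone(est)
        assert cloned.get_params()["sizes"] == (1, 2)
        est.fit(fm.values, fm.outcome)
        assert len(est.results_) == 3 + 3
        preds = est.predict(fm.values)
        assert preds.shape == (12,)


class TestPredictExternal:
    def _model(self):
        return ModelFit(
            predictors=("naiveCD4T", "TMB"),
            coefficients={"naiveCD4T": 24.41, "TMB": 1.01},
            intercept=-2.09, rss=np.nan, loglik=np.nan, n=21,
            loocv_r=np.nan, loocv_p=np.nan, unexplained_variance=np.nan,
        )

    def test_zero_inputs_return_intercept(self):
        assert predict_external(self._model(), {"naiveCD4T": 0, "TMB": 0}) == -2.09

    def test_printed_bivariate_coefficients_arithmetic(self):
        # 24.41 * 0.1 + 1.01 * 1 - 2.09
        value = predict_external(self._model(), {"naiveCD4T": 0.1, "TMB": 1.0})
        assert value == pytest.approx(1.361, abs=1e-12)

    def test_linearity(self, rng):
        model = self._model()
        x = {"naiveCD4T": 0.37, "TMB": 1.9}
        zero = predict_external(model, {k: 0.0 for k in x})
        full = predict_external(model, x)
        half = predict_external(model, {k: v / 2 for k, v in x.items()})
        assert half - zero == pytest.approx((full - zero) / 2, rel=1e-12)

    def test_missing_predictor_named(self):
        with pytest.raises(InputError, match="TMB"):
            predict_external(self._model(), {"naiveCD4T": 0.1})


def test_unexplained_variance_bounds():
    assert unexplained_variance(1.0) == pytest.approx(0.0)
    assert unexplained_variance(0.0) == pytest.approx(1.0)
    with pytest.raises(InputError):
        unexplained_variance(1.5)
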