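"""Exhaustive multivariable linear-model search for irAE risk prediction.

Candidate factor subsets of size 1–3 (configurable) are fitted by ordinary
least squares against the per-cancer ROR.  Each model is scored by the
Pearson correlation between leave-one-cancer-type-out predictions and the
observed ROR (the field-standard LOOCV R), screened for multicollinearity by
variance inflation factors (VIF > 4 flags a model), and compared with every
one-smaller nested parent by a Gaussian log-likelihood ratio test against a
chi-square reference.  Reported coefficients always come from the full-data
fit; predictive performance always from the held-out predictions.

The LOOCV predictions are computed through the exact leverage identity for
linear smoothers, ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ), which is algebraically equal to
refitting each fold from scratch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateInputError,
    FoldFailureError,
    InputError,
    NestingError,
    SingularDesignError,
)
from .features import FactorMatrix
from .screen import bh_adjust, pearson_r_p

#: Floor for the ML variance estimate when a fit is exact (RSS = 0).
SIGMA2_FLOOR = 1e-12


def _gaussian_loglik(rss: float, n: int, sigma2_floor: float) -> tuple[float, bool]:
    sigma2 = rss / n
    degenerate = sigma2 < sigma2_floor
    sigma2 = max(sigma2, sigma2_floor)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0), degenerate


class LinearRiskModel(RegressorMixin, BaseEstimator):
    """OLS risk model with leverage-based LOOCV scoring and VIF diagnostics.

    Parameters
    ----------
    sigma2_floor : float
        Lower bound on the ML variance estimate; an exact fit (RSS = 0) is
        floored here and flagged via ``degenerate_fit_`` instead of producing
        an infinite log-likelihood.
    compute_loocv : bool
        Whether ``fit`` also computes held-out predictions and their Pearson
        correlation with the observed outcome (requires n ≥ 4).

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : full-data OLS solution
    rss_, loglik_ : residual sum of squares and Gaussian ML log-likelihood
    loocv_predictions_, loocv_r_, loocv_p_ : held-out performance
    vif_ : per-predictor variance inflation factors (≥ 2 predictors)
    """

    def __init__(self, sigma2_floor: float = SIGMA2_FLOOR, compute_loocv: bool = True):
        self.sigma2_floor = sigma2_floor
        self.compute_loocv = compute_loocv

    def fit(self, X, y) -> "LinearRiskModel":
        X = pd.DataFrame(X).copy()
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if y.shape != (n,):
            raise InputError("X and y have inconsistent lengths")
        if np.isnan(X.to_numpy(dtype=float)).any() or np.isnan(y).any():
            raise InputError("missing values in the design or outcome")
        if n <= p + 1:
            raise InputError(f"need n > p + 1 observations (n={n}, p={p})")
        design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(design) < p + 1:
            raise SingularDesignError("design matrix is rank deficient")

        res = sm.OLS(y, design).fit()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = p
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.rss_ = float(res.ssr)
        self.n_ = n
        self.loglik_, self.degenerate_fit_ = _gaussian_loglik(
            self.rss_, n, self.sigma2_floor
        )
        self.vif_ = vif(X) if p >= 2 else {}

        if self.compute_loocv and n >= 4:
            hat = res.get_influence().hat_matrix_diag
            bad = np.flatnonzero(hat > 1.0 - 1e-8)
            if bad.size:
                raise FoldFailureError(
                    f"LOOCV fold {bad[0]} is singular (leverage 1)"
                )
            loo = y - res.resid / (1.0 - hat)
            self.loocv_predictions_ = loo
            try:
                self.loocv_r_, self.loocv_p_ = pearson_r_p(loo, y)
            except DegenerateInputError:
                self.loocv_r_ = self.loocv_p_ = float("nan")
        else:
            self.loocv_predictions_ = None
            self.loocv_r_ = self.loocv_p_ = float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_) and set(
            X.columns
        ) >= set(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_


def fit_ols(X, y, sigma2_floor: float = SIGMA2_FLOOR):
    """Full-data OLS fit: (coefficients, intercept, rss, loglik).

    The log-likelihood is the Gaussian maximum-likelihood value
    ℓ = −(n/2)(ln(2π σ̂²) + 1) with σ̂² = RSS/n.
    """
    model = LinearRiskModel(sigma2_floor=sigma2_floor, compute_loocv=False).fit(X, y)
    coefficients = dict(zip(model.feature_names_in_, model.coef_))
    return coefficients, model.intercept_, model.rss_, model.loglik_


def loocv_r(X, y):
    """Leave-one-out predictions and their Pearson (r, p) against y."""
    X = pd.DataFrame(X)
    if len(X) < 4:
        raise InputError("LOOCV requires n >= 4")
    model = LinearRiskModel().fit(X, y)
    return model.loocv_r_, model.loocv_p_, model.loocv_predictions_


def vif(X) -> dict[str, float]:
    """Variance inflation factors: 1/(1 − R²ⱼ), predictor j on the others.

    Each auxiliary regression includes an intercept.  Perfect collinearity is
    reported as an infinite VIF, not an exception.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise InputError("VIF needs at least two predictors")
    out: dict[str, float] = {}
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(len(X)), others])
        res = sm.OLS(arr[:, j], design).fit()
        r2 = float(res.rsquared)
        out[str(name)] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class ModelFit:
    """One candidate linear model with its selection diagnostics."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    rss: float
    loglik: float
    n: int
    loocv_r: float
    loocv_p: float
    unexplained_variance: float
    vif: dict[str, float] = field(default_factory=dict)
    lr_tests: dict[tuple[str, ...], tuple[float, float]] = field(default_factory=dict)
    fdr: float = float("nan")
    degenerate: bool = False
    admissible: bool = True

    @property
    def vif_max(self) -> float:
        return max(self.vif.values()) if self.vif else float("nan")


def lr_test(full: ModelFit, reduced: ModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested OLS-ML fits: Λ = 2(ℓ_full − ℓ_reduced).

    p comes from a chi-square with df = number of extra predictors.
    """
    full_set, reduced_set = set(full.predictors), set(reduced.predictors)
    if not reduced_set < full_set:
        raise NestingError(
            f"{reduced.predictors} is not a proper subset of {full.predictors}"
        )
    if full.n != reduced.n:
        raise NestingError("nested models must be fit on the same observations")
    lam = 2.0 * (full.loglik - reduced.loglik)
    lam = max(lam, 0.0)  # guard float round-off; true nested ML gives Λ ≥ 0
    df = len(full_set) - len(reduced_set)
    return lam, float(stats.chi2.sf(lam, df))


def predict_external(model: ModelFit, external_medians: Mapping[str, float]) -> float:
    """Apply the full-data coefficients to external per-cancer medians."""
    total = model.intercept
    for name in model.predictors:
        if name not in external_medians:
            raise InputError(f"external medians lack predictor {name!r}")
        total += model.coefficients[name] * float(external_medians[name])
    return float(total)


def _fit_subset(
    X: pd.DataFrame, y: np.ndarray, predictors: tuple[str, ...], sigma2_floor: float
) -> ModelFit:
    sub = X[list(predictors)]
    est = LinearRiskModel(sigma2_floor=sigma2_floor).fit(sub, y)
    r = est.loocv_r_
    return ModelFit(
        predictors=predictors,
        coefficients=dict(zip(predictors, est.coef_)),
        intercept=est.intercept_,
        rss=est.rss_,
        loglik=est.loglik_,
        n=est.n_,
        loocv_r=r,
        loocv_p=est.loocv_p_,
        unexplained_variance=float(1.0 - r**2) if np.isfinite(r) else float("nan"),
        vif=est.vif_,
        degenerate=est.degenerate_fit_,
    )


class ExhaustiveModelSearch(BaseEstimator):
    """Enumerate all factor subsets of the requested sizes and rank them.

    Sklearn-style meta-estimator: ``fit(X, y)`` with X a cancer-type × factor
    DataFrame fits every size-k subset of ``candidates`` (k in ``sizes``),
    stores the ranked list in ``results_``, and exposes the best model in
    ``best_model_``.  Ranking is by LOOCV R descending, ties broken by fewer
    predictors then lexicographic predictor names.  A model is admissible iff
    every nested-parent likelihood-ratio test has p < ``lr_alpha`` and no
    VIF exceeds ``vif_limit``.  BH adjustment of the LOOCV p-values is done
    within each model-size family.
    """

    def __init__(
        self,
        candidates: Sequence[str] | None = None,
        sizes: Sequence[int] = (1, 2, 3),
        vif_limit: float = 4.0,
        lr_alpha: float = 0.05,
        sigma2_floor: float = SIGMA2_FLOOR,
    ):
        self.candidates = candidates
        self.sizes = sizes
        self.vif_limit = vif_limit
        self.lr_alpha = lr_alpha
        self.sigma2_floor = sigma2_floor

    def fit(self, X, y) -> "ExhaustiveModelSearch":
        X = pd.DataFrame(X)
        candidates = list(self.candidates) if self.candidates is not None else list(X.columns)
        missing = [c for c in candidates if c not in X.columns]
        if missing:
            raise InputError(f"candidate factors absent from the matrix: {missing}")
        sizes = sorted(set(int(k) for k in self.sizes))
        if not sizes or sizes[0] < 1:
            raise InputError("model sizes must be positive integers")

        sub = X[candidates].copy()
        y = pd.Series(np.asarray(y, dtype=float), index=sub.index)
        complete = sub.notna().all(axis=1) & y.notna()
        sub, yv = sub.loc[complete], y.loc[complete].to_numpy()
        n = len(sub)
        if sizes[-1] >= n - 2:
            raise InputError(
                f"largest model size {sizes[-1]} needs more than {sizes[-1] + 2} "
                f"complete cancer types, have {n}"
            )

        cache: dict[tuple[str, ...], ModelFit] = {}

        def fitted(preds: tuple[str, ...]) -> ModelFit:
            if preds not in cache:
                if preds:
                    cache[preds] = _fit_subset(sub, yv, preds, self.sigma2_floor)
                else:
                    est = LinearRiskModel(
                        sigma2_floor=self.sigma2_floor, compute_loocv=False
                    ).fit(sub[[]], yv)
                    cache[preds] = ModelFit(
                        predictors=(), coefficients={}, intercept=est.intercept_,
                        rss=est.rss_, loglik=est.loglik_, n=est.n_,
                        loocv_r=float("nan"), loocv_p=float("nan"),
                        unexplained_variance=float("nan"),
                        degenerate=est.degenerate_fit_,
                    )
            return cache[preds]

        by_size: dict[int, list[ModelFit]] = {}
        for k in range(1, sizes[-1] + 1):
            for combo in itertools.combinations(sorted(candidates), k):
                mf = fitted(combo)
                for parent in itertools.combinations(combo, k - 1):
                    mf.lr_tests[parent] = lr_test(mf, fitted(parent))
                mf.admissible = all(
                    p < self.lr_alpha for _, p in mf.lr_tests.values()
                ) and not any(v > self.vif_limit for v in mf.vif.values())
                by_size.setdefault(k, []).append(mf)

        results: list[ModelFit] = []
        for k in sizes:
            fits = by_size.get(k, [])
            pvals = np.array([m.loocv_p for m in fits])
            ok = np.isfinite(pvals)
            if ok.any():
                adj = bh_adjust(pvals[ok])
                for m, a in zip(np.array(fits, dtype=object)[ok], adj):
                    m.fdr = float(a)
            results.extend(fits)

        results.sort(
            key=lambda m: (
                -(m.loocv_r if np.isfinite(m.loocv_r) else -np.inf),
                len(m.predictors),
                m.predictors,
            )
        )
        self.results_ = results
        self.n_types_ = n
        self.best_by_size_ = {}
        for m in results:
            self.best_by_size_.setdefault(len(m.predictors), m)
        admissible = [m for m in results if m.admissible]
        self.best_model_ = admissible[0] if admissible else results[0]
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        best = self.best_model_
        cols = X[list(best.predictors)].to_numpy(dtype=float)
        coef = np.array([best.coefficients[p] for p in best.predictors])
        return best.intercept + cols @ coef

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.results_:
            rows.append(
                {
                    "predictors": "+".join(m.predictors),
                    "size": len(m.predictors),
                    "intercept": m.intercept,
                    "coefficients": ";".join(
                        f"{k}={v:.6g}" for k, v in m.coefficients.items()
                    ),
                    "loocv_r": m.loocv_r,
                    "loocv_p": m.loocv_p,
                    "fdr": m.fdr,
                    "unexplained_variance": m.unexplained_variance,
                    "vif_max": m.vif_max,
                    "lr_parent_p_max": max(
                        (p for _, p in m.lr_tests.values()), default=float("nan")
                    ),
                    "admissible": m.admissible,
                }
            )
        return pd.DataFrame(rows)


def enumerate_and_rank(
    fm: FactorMatrix,
    candidates: Sequence[str] | None = None,
    sizes: Sequence[int] = (1, 2, 3),
    vif_limit: float = 4.0,
    lr_alpha: float = 0.05,
) -> list[ModelFit]:
    """Functional wrapper around :class:`ExhaustiveModelSearch`."""
    search = ExhaustiveModelSearch(
        candidates=candidates, sizes=sizes, vif_limit=vif_limit, lr_alpha=lr_alpha
    ).fit(fm.values, fm.outcome)
    return search.results_


def unexplained_variance(r: float) -> float:
    """Bookkeeping helper: 1 − R² for a reported prediction correlation."""
    if not np.isfinite(r) or abs(r) > 1:
        raise InputError("correlation must lie in [-1, 1]")
    return 1.0 - r * r


def variance_explained_percent(r: float) -> float:
    """R² expressed as a percentage of outcome variance explained."""
    if not np.isfinite(r) or abs(r) > 1:
        raise InputError("correlation must lie in [-1, 1]")
    return 100.0 * r * r
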