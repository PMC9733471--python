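"""Across-cancer-type correlation screening with BH FDR control.

Each factor's per-cancer median is correlated with the ROR outcome by Pearson
correlation (two-sided p from the t-distribution on n−2 df).  The
Benjamini-Hochberg step-up adjustment is applied within screening families:
the curated immunogenomic panel forms one family and each molecular omics
kind (mRNA, microRNA, protein, phosphoprotein) its own, since the genome-wide
screens have very different multiplicities than the hand-picked panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError
from .features import FactorMatrix


@dataclass(frozen=True)
class CorrelationResult:
    factor: str
    family: str
    n: int
    r: float
    p: float
    fdr: float
    reason: str | None = None


def pearson_r_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t reference, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson_r_p requires two equal-length vectors")
    if x.size < 3:
        raise InputError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, mapped to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_factors(
    fm: FactorMatrix,
    families: Mapping[str, str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlate every factor with the outcome, BH-adjusted within family.

    Missing values are handled by pairwise-complete deletion per factor with
    the effective n recorded.  Factors with fewer than ``min_n`` complete
    pairs or a constant column are reported with a reason and excluded from
    the FDR multiplicity of their family.
    """
    if fm.values.shape[1] == 0:
        raise InputError("factor matrix has no factor columns")
    families = dict(families) if families is not None else dict(fm.families)
    rows: list[dict] = []
    for factor in fm.values.columns:
        col = fm.values[factor]
        mask = col.notna() & fm.outcome.notna()
        family = families.get(factor, "panel")
        n = int(mask.sum())
        if n < min_n:
            rows.append(dict(factor=factor, family=family, n=n, r=np.nan,
                             p=np.nan, fdr=np.nan, reason=f"n={n} < {min_n}"))
            continue
        x = col[mask].to_numpy(dtype=float)
        y = fm.outcome[mask].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(dict(factor=factor, family=family, n=n, r=np.nan,
                             p=np.nan, fdr=np.nan, reason="constant vector"))
            continue
        r, p = pearson_r_p(x, y)
        rows.append(dict(factor=factor, family=family, n=n, r=r, p=p,
                         fdr=np.nan, reason=None))
    out = pd.DataFrame(rows)
    for family, idx in out.groupby("family").groups.items():
        ok = out.loc[idx, "p"].notna()
        valid = out.loc[idx][ok].index
        if len(valid):
            out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["abs_r"] = out["r"].abs()
    out = out.sort_values("abs_r", ascending=False, kind="stable").drop(columns="abs_r")
    return out.reset_index(drop=True)


class CorrelationScreen(BaseEstimator):
    """Feature screening by across-group Pearson correlation with the outcome.

    Sklearn-style selector: ``fit(X, y)`` with X a cancer-type × factor
    DataFrame stores the per-factor correlation table in ``results_``;
    ``transform`` keeps the factors passing the family-wise BH threshold.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance threshold used by ``transform``.
    families : mapping factor → family, optional
        FDR family labels; unlisted factors fall into the ``"panel"`` family.
    min_n : int
        Minimum pairwise-complete observations per factor.
    """

    def __init__(self, alpha: float = 0.05, families: Mapping[str, str] | None = None,
                 min_n: int = 3):
        self.alpha = alpha
        self.families = families
        self.min_n = min_n

    def fit(self, X: pd.DataFrame, y) -> "CorrelationScreen":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        fm = FactorMatrix(values=X, outcome=y,
                          families=dict(self.families) if self.families else {})
        self.results_ = screen_factors(fm, families=self.families, min_n=self.min_n)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        sig = self.results_[self.results_["fdr"] < self.alpha]
        self.selected_factors_ = list(sig["factor"])
        return self

    def get_support(self) -> np.ndarray:
        selected = set(self.selected_factors_)
        return np.array([f in selected for f in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=self.feature_names_in_)
        return X[[f for f in self.feature_names_in_ if f in set(self.selected_factors_)]]
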