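"""Independent-cohort validation of candidate irAE-risk genes.

Patients carry an immunotherapy class (anti–PD-1 monotherapy or combination),
a worst irAE grade on the CTCAE 0–4 scale (grade 0 = no toxicity, occurrence
= grade ≥ 1), and gene expression in TPM.  Candidate genes are tested by
Mann-Whitney U between irAE-positive and irAE-free patients, by a logistic
regression of irAE occurrence on expression adjusting for therapy class, and
by grade-wise pairwise comparisons against a reference grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateGroupError,
    FeatureMissingError,
    InputError,
    SingularDesignError,
)

THERAPY_CLASSES = ("anti-PD-1", "combination")

#: Switch to the normal approximation above this n1*n2 (or with any tie).
EXACT_LIMIT = 400


@dataclass
class CohortTable:
    """Validation-cohort patients: metadata plus a gene × patient TPM matrix."""

    meta: pd.DataFrame  # patient_id, therapy_class, irae_grade
    expression: pd.DataFrame  # genes × patients, TPM

    def __post_init__(self) -> None:
        required = {"patient_id", "therapy_class", "irae_grade"}
        if not required <= set(self.meta.columns):
            raise InputError(f"cohort metadata needs columns {sorted(required)}")
        if self.meta["patient_id"].duplicated().any():
            raise InputError("patient_id values must be unique")
        grades = self.meta["irae_grade"]
        if not grades.isin(range(5)).all():
            raise InputError("irAE grades must be integers in 0..4")
        if (self.expression < 0).any().any():
            raise InputError("TPM values must be non-negative")
        missing = set(self.meta["patient_id"]) - set(self.expression.columns)
        if missing:
            raise InputError(f"patients without expression: {sorted(missing)[:5]}")

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.expression.index:
            raise FeatureMissingError(f"gene {gene!r} absent from the cohort matrix")
        return self.expression.loc[gene, self.meta["patient_id"]]

    def irae_status(self, grade_cut: int = 1) -> pd.Series:
        return (self.meta.set_index("patient_id")["irae_grade"] >= grade_cut).astype(int)


def read_cohort(meta_path: str | Path, expr_path: str | Path) -> CohortTable:
    meta = pd.read_csv(meta_path, sep="\t")
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    return CohortTable(meta=meta, expression=expr)


def write_cohort(cohort: CohortTable, meta_path: str | Path, expr_path: str | Path) -> None:
    cohort.meta.to_csv(meta_path, sep="\t", index=False)
    cohort.expression.to_csv(expr_path, sep="\t")


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    group_labels: tuple[str, str]
    group_medians: tuple[float, float]
    u: float
    p: float
    n: tuple[int, int]
    adjusted_association: tuple[float, float] | None = None


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and a two-sided p-value.

    U counts, over all cross pairs, a > b plus half the ties.  The p-value is
    exact (full enumeration of labelings) when n1·n2 ≤ 400 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateGroupError("Mann-Whitney requires two nonempty groups")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def irae_association(
    cohort: CohortTable, gene: str, grade_cut: int = 1
) -> GroupComparison:
    """Expression difference between irAE-positive (grade ≥ cut) and irAE-free."""
    values = cohort.gene_values(gene)
    status = cohort.irae_status(grade_cut).to_numpy()
    pos = values.to_numpy(dtype=float)[status == 1]
    neg = values.to_numpy(dtype=float)[status == 0]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateGroupError(
            "both irAE-positive and irAE-free patients are required"
        )
    u, p = mann_whitney(pos, neg)
    return GroupComparison(
        gene=gene,
        group_labels=("irAE", "no irAE"),
        group_medians=(float(np.median(pos)), float(np.median(neg))),
        u=u,
        p=p,
        n=(int(pos.size), int(neg.size)),
    )


def adjusted_association(
    cohort: CohortTable, gene: str, grade_cut: int = 1, maxiter: int = 100
) -> tuple[float, float]:
    """Therapy-class-adjusted logistic association of expression with irAE.

    Fits irAE ~ intercept + expression + therapy-class indicator by maximum
    likelihood (IRLS/Newton) and returns the expression coefficient with its
    two-sided Wald p-value.
    """
    values = cohort.gene_values(gene).to_numpy(dtype=float)
    status = cohort.irae_status(grade_cut).to_numpy()
    if status.min() == status.max():
        raise DegenerateGroupError("irAE outcome is constant in the cohort")
    therapy = (
        cohort.meta["therapy_class"].to_numpy() == cohort.meta["therapy_class"].iloc[0]
    ).astype(float)
    columns = [np.ones(len(values)), values]
    if therapy.min() != therapy.max():  # indicator only when both classes occur
        columns.append(therapy)
    design = np.column_stack(columns)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularDesignError(
            "expression and therapy class are confounded (rank-deficient design)"
        )
    try:
        res = sm.Logit(status, design).fit(disp=0, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 50:
        raise ConvergenceError(
            "logistic fit did not converge (possible complete separation)"
        )
    return float(res.params[1]), float(res.pvalues[1])


def grade_comparisons(
    cohort: CohortTable, gene: str, reference_grade: int = 4
) -> list[GroupComparison]:
    """Per-grade medians and pairwise tests against the reference grade."""
    values = cohort.gene_values(gene)
    grades = cohort.meta.set_index("patient_id")["irae_grade"]
    ref = values[grades[values.index] == reference_grade].to_numpy(dtype=float)
    if ref.size == 0:
        raise DegenerateGroupError(f"no patients at reference grade {reference_grade}")
    present = sorted(g for g in grades.unique() if g != reference_grade)
    if not present:
        raise DegenerateGroupError("all patients share the reference grade")
    out = []
    for g in present:
        other = values[grades[values.index] == g].to_numpy(dtype=float)
        u, p = mann_whitney(other, ref)
        out.append(
            GroupComparison(
                gene=gene,
                group_labels=(f"grade {g}", f"grade {reference_grade}"),
                group_medians=(float(np.median(other)), float(np.median(ref))),
                u=u,
                p=p,
                n=(int(other.size), int(ref.size)),
            )
        )
    return out


def validate_genes(
    cohort: CohortTable,
    genes: Sequence[str],
    grade_cut: int = 1,
    adjust_therapy: bool = True,
) -> pd.DataFrame:
    """Run the irAE association (and optional therapy adjustment) per gene."""
    rows = []
    for gene in genes:
        cmp = irae_association(cohort, gene, grade_cut=grade_cut)
        row = {
            "gene": gene,
            "median_irae": cmp.group_medians[0],
            "median_no_irae": cmp.group_medians[1],
            "U": cmp.u,
            "p": cmp.p,
            "n_irae": cmp.n[0],
            "n_no_irae": cmp.n[1],
        }
        if adjust_therapy:
            try:
                coef, p_adj = adjusted_association(cohort, gene, grade_cut=grade_cut)
                row["adjusted_coef"], row["adjusted_p"] = coef, p_adj
            except (ConvergenceError, SingularDesignError):
                row["adjusted_coef"] = row["adjusted_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
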