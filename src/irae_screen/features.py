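"""Per-patient immunogenomic factors and per-cancer-type aggregation.

Factors mirror the usual pan-cancer correlates of checkpoint-inhibitor
response: tumor mutational burden (log-transformed nonsynonymous mutation
count), xCell-style immune-cell enrichment scores in [0, 1], expression
signatures scored from gene sets, checkpoint-gene expression, and the
proportion of PD-1-high patients per cancer type.  Everything except the
PD-1-high proportion is aggregated to a per-cancer-type median; the result is
a cancer-type × factor matrix aligned with the per-cancer ROR outcome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FeatureMissingError,
    InputError,
    InsufficientGroupsError,
)
from .pharmacovigilance import RORResult

logger = logging.getLogger(__name__)

PATIENT_FIXED_COLUMNS = ("patient_id", "cancer_type", "nonsynonymous_mutation_count")
EXTRA_FACTOR_PREFIX = "extra_"

OMICS_KINDS = ("mrna", "mirna", "protein", "phosphoprotein")


def compute_tmb(count: float, base: float = 10.0, offset: float = 1.0) -> float:
    """Log-transformed tumor mutational burden: log_base(count + offset)."""
    if count < 0:
        raise InputError(f"mutation count must be non-negative, got {count}")
    return math.log(count + offset, base)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    scoring: str = "mean_log"  # or "geometric_mean"

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        if self.scoring not in ("mean_log", "geometric_mean"):
            raise InputError(f"unknown scoring rule {self.scoring!r}")


def read_gmt(path: str | Path, scoring: Mapping[str, str] | str = "mean_log") -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, tab-separated ids).

    ``scoring`` is either one rule for all sets or a mapping set-name → rule.
    """
    sets = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = parts
        rule = scoring if isinstance(scoring, str) else scoring.get(name, "mean_log")
        sets.append(GeneSet(name=name, genes=frozenset(g for g in genes if g), scoring=rule))
    return sets


@dataclass
class ExpressionMatrix:
    """Feature × patient expression values of one omics kind, values ≥ 0."""

    values: pd.DataFrame
    kind: str = "mrna"

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise InputError(f"unknown omics kind {self.kind!r}")
        if self.values.index.duplicated().any():
            raise InputError("duplicate feature ids in expression matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns


def read_expression(path: str | Path, kind: str = "mrna") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, kind=kind)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def signature_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    epsilon: float = 0.01,
) -> pd.Series:
    """Score every patient on a gene set.

    mean_log: arithmetic mean of log2(value + 1) over set genes.
    geometric_mean: exp(mean(ln(value + epsilon))), the cytolytic-index
    convention with its small pseudocount.
    Genes absent from the matrix are dropped with a warning; if none remain,
    the signature cannot be scored.
    """
    present = [g for g in sorted(gene_set.genes) if g in expr.values.index]
    missing = gene_set.genes - set(present)
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes absent from %s matrix",
            gene_set.name, len(missing), len(gene_set.genes), expr.kind,
        )
    if not present:
        raise FeatureMissingError(
            f"no gene of set {gene_set.name!r} present in the {expr.kind} matrix"
        )
    sub = expr.values.loc[present]
    if gene_set.scoring == "geometric_mean":
        return np.exp(np.log(sub + epsilon).mean(axis=0)).rename(gene_set.name)
    return np.log2(sub + 1.0).mean(axis=0).rename(gene_set.name)


def pd1_high_proportion(
    expr: ExpressionMatrix,
    cancer_types: pd.Series,
    gene_id: str = "PDCD1",
    percentile: float = 80.0,
) -> pd.Series:
    """Per-cancer-type fraction of patients strictly above the pooled cutoff.

    The cutoff is the linear-interpolation percentile of the gene's expression
    pooled over all patients; "strictly above" keeps the all-equal case at 0.
    """
    if not 0 < percentile < 100:
        raise InputError("percentile must lie in (0, 100)")
    if gene_id not in expr.values.index:
        raise FeatureMissingError(f"gene {gene_id!r} absent from {expr.kind} matrix")
    values = expr.values.loc[gene_id]
    cancer_types = cancer_types.reindex(values.index)
    if cancer_types.isna().any():
        raise InputError("every patient in the expression matrix needs a cancer type")
    cutoff = float(np.percentile(values.to_numpy(dtype=float), percentile))
    high = values > cutoff
    return high.groupby(cancer_types).mean().rename("PD1_high_proportion")


def preprocess_expression(
    expr: ExpressionMatrix,
    cancer_types: pd.Series,
    zero_median_fraction: float = 0.5,
) -> ExpressionMatrix:
    """log2(x+1) transform and low-expression feature filtering.

    A feature is dropped when its per-cancer-type median is zero in more than
    ``zero_median_fraction`` of cancer types.  Each omics kind is processed
    independently of the others.
    """
    cancer_types = cancer_types.reindex(expr.values.columns)
    if cancer_types.isna().any():
        raise InputError("every patient in the expression matrix needs a cancer type")
    medians = expr.values.T.groupby(cancer_types).median().T  # features × types
    zero_frac = (medians == 0).mean(axis=1)
    keep = zero_frac <= zero_median_fraction
    if not keep.any():
        raise DegenerateInputError(
            f"all {expr.kind} features removed by the zero-median filter"
        )
    transformed = np.log2(expr.values.loc[keep] + 1.0)
    return ExpressionMatrix(values=transformed, kind=expr.kind)


@dataclass
class FactorMatrix:
    """Cancer-type × factor medians with the aligned ROR outcome vector."""

    values: pd.DataFrame
    outcome: pd.Series
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.outcome.index):
            raise InputError("factor matrix and outcome are not aligned")
        if self.outcome.isna().any():
            raise InputError("outcome vector has missing entries")

    @property
    def cancer_types(self) -> pd.Index:
        return self.values.index

    @property
    def factors(self) -> pd.Index:
        return self.values.columns

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "ROR", self.outcome)
        return out


def validate_patients(patients: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PATIENT_FIXED_COLUMNS[:2] if c not in patients.columns]
    if missing:
        raise InputError(f"patient table is missing columns: {missing}")
    if patients["patient_id"].duplicated().any():
        raise InputError("patient_id values must be unique")
    for col in _abundance_columns(patients):
        vals = patients[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise InputError(f"enrichment scores in column {col!r} must lie in [0, 1]")
    return patients


def _abundance_columns(patients: pd.DataFrame) -> list[str]:
    return [
        c
        for c in patients.columns
        if c not in PATIENT_FIXED_COLUMNS and not c.startswith(EXTRA_FACTOR_PREFIX)
    ]


def median_factor_matrix(
    patients: pd.DataFrame,
    omics: Mapping[str, ExpressionMatrix],
    signatures: Sequence[GeneSet],
    ror_results: Sequence[RORResult],
    pd1_gene: str = "PDCD1",
    checkpoint_genes: Mapping[str, str] | None = None,
    pd1_percentile: float = 80.0,
    tmb_base: float = 10.0,
    min_shared_types: int = 3,
    include_molecular: bool = True,
) -> FactorMatrix:
    """Aggregate per-patient factors to the per-cancer-type median matrix.

    Curated panel factors (TMB, cell abundances, signatures, checkpoint genes,
    PD-1-high proportion, ``extra_*`` columns) share one screening family;
    molecular features (every preprocessed feature of each omics kind) are
    added as ``<kind>:<feature>`` columns, each kind its own family.  Cancer
    types without an ROR (or vice versa) are dropped with a warning.
    """
    validate_patients(patients)
    if checkpoint_genes is None:
        checkpoint_genes = {"PD1_mRNA": pd1_gene, "PDL1_mRNA": "CD274"}
    groups = patients["cancer_type"]
    indexed = patients.set_index("patient_id")
    per_patient: dict[str, pd.Series] = {}
    families: dict[str, str] = {}

    if "nonsynonymous_mutation_count" in patients.columns:
        counts = indexed["nonsynonymous_mutation_count"]
        per_patient["TMB"] = counts.map(
            lambda c: compute_tmb(c, base=tmb_base) if pd.notna(c) else np.nan
        )
        families["TMB"] = "panel"
    for col in _abundance_columns(patients):
        per_patient[col] = indexed[col]
        families[col] = "panel"
    for col in patients.columns:
        if col.startswith(EXTRA_FACTOR_PREFIX):
            name = col[len(EXTRA_FACTOR_PREFIX):]
            per_patient[name] = indexed[col]
            families[name] = "panel"

    patient_types = indexed["cancer_type"]
    mrna = omics.get("mrna")
    processed: dict[str, ExpressionMatrix] = {}
    for kind, expr in omics.items():
        processed[kind] = preprocess_expression(
            expr, patient_types.reindex(expr.values.columns)
        )

    if mrna is not None:
        for sig in signatures:
            per_patient[sig.name] = signature_score(mrna, sig)
            families[sig.name] = "panel"
        for factor_name, gene in checkpoint_genes.items():
            if gene in processed["mrna"].values.index:
                per_patient[factor_name] = processed["mrna"].values.loc[gene]
                families[factor_name] = "panel"
            else:
                logger.warning("checkpoint gene %s absent; factor %s skipped", gene, factor_name)

    ror_series = pd.Series(
        {r.cancer_type: r.ror for r in ror_results}, name="ROR", dtype=float
    )
    shared = sorted(set(groups.unique()) & set(ror_series.index))
    dropped = (set(groups.unique()) | set(ror_series.index)) - set(shared)
    if dropped:
        logger.warning("cancer types without both cohort and ROR dropped: %s", sorted(dropped))
    if len(shared) < min_shared_types:
        raise InsufficientGroupsError(
            f"only {len(shared)} cancer types shared between cohort and ROR table"
        )

    factor_df = pd.DataFrame(per_patient)
    factor_df["cancer_type"] = patient_types
    medians = factor_df.groupby("cancer_type").median().loc[shared]

    if mrna is not None and pd1_gene in mrna.values.index:
        prop = pd1_high_proportion(
            mrna, patient_types.reindex(mrna.values.columns),
            gene_id=pd1_gene, percentile=pd1_percentile,
        )
        medians["PD1_high_proportion"] = prop.reindex(shared)
        families["PD1_high_proportion"] = "panel"

    if include_molecular:
        for kind, expr in processed.items():
            types = patient_types.reindex(expr.values.columns)
            kind_medians = expr.values.T.groupby(types).median().loc[shared]
            kind_medians.columns = [f"{kind}:{f}" for f in kind_medians.columns]
            for col in kind_medians.columns:
                families[col] = kind
            medians = pd.concat([medians, kind_medians], axis=1)

    return FactorMatrix(
        values=medians,
        outcome=ror_series.reindex(shared),
        families=families,
    )
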