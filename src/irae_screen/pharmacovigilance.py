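"""Disproportionality analysis of spontaneous adverse-event reports.

The unit of analysis is a spontaneous report (one row) carrying the suspected
drugs, the cancer indication, and a set of MedDRA-style reaction preferred
terms.  The stage filters reports to the anti–PD-1 monotherapy stratum,
classifies each report as irAE-positive if at least one reaction matches a
curated preferred-term list, and computes a reporting odds ratio (ROR) per
cancer type from the 2×2 table

    a = irAE reports, index cancer type
    b = non-irAE reports, index cancer type
    c = irAE reports, comparator stratum (all other cancer types)
    d = non-irAE reports, comparator stratum

with ROR = (a·d)/(b·c) and a 95% Wald interval on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InputError,
    InsufficientGroupsError,
    UndefinedStatisticError,
)

REPORT_COLUMNS = ("report_id", "suspected_drugs", "indication", "reactions")

#: z quantile for the conventional two-sided 95% Wald interval.
Z_95 = 1.959963984540054


def _normalize_term(term: str) -> str:
    return term.strip().casefold()


@dataclass(frozen=True)
class IraeTermList:
    """A normalized set of irAE preferred terms.

    Matching is exact after case-folding and whitespace trimming; preferred
    terms are controlled vocabulary, so no fuzzy matching is attempted.
    """

    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise InputError("irAE term list must be nonempty")

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "IraeTermList":
        normalized = {_normalize_term(t) for t in terms if _normalize_term(t)}
        return cls(frozenset(normalized))

    @classmethod
    def from_file(cls, path: str | Path) -> "IraeTermList":
        """Read one term per line; ``#`` starts a comment."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        terms = [ln.split("#", 1)[0] for ln in lines]
        return cls.from_terms(t for t in terms if t.strip())

    def __contains__(self, term: str) -> bool:
        return _normalize_term(term) in self.terms

    def matches(self, reactions: Iterable[str]) -> bool:
        return any(_normalize_term(r) in self.terms for r in reactions)


def classify_irae(reactions: Iterable[str], terms: IraeTermList) -> bool:
    """True iff at least one reaction is on the irAE term list."""
    reactions = list(reactions)
    if not reactions:
        raise InputError("report has an empty reaction list")
    return terms.matches(reactions)


@dataclass(frozen=True)
class ContingencyTable:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")


@dataclass(frozen=True)
class RORResult:
    """Per-cancer-type reporting odds ratio with its 95% Wald interval."""

    cancer_type: str | None
    ror: float
    ci_low: float
    ci_high: float
    table: ContingencyTable
    n_reports: int
    n_irae: int
    corrected: bool = field(default=False)


def ror_from_counts(
    a: float,
    b: float,
    c: float,
    d: float,
    correction: str = "haldane",
    cancer_type: str | None = None,
) -> RORResult:
    """Reporting odds ratio and 95% CI from a 2×2 table.

    ``correction='haldane'`` adds 0.5 to all four cells, but only when some
    cell is zero; ``correction='none'`` raises if the statistic is undefined.
    """
    table = ContingencyTable(a, b, c, d)
    counts = np.array([a, b, c, d], dtype=float)
    corrected = False
    if correction == "haldane" and (counts == 0).any():
        counts = counts + 0.5
        corrected = True
    elif correction not in ("haldane", "none"):
        raise InputError(f"unknown correction rule: {correction!r}")
    ca, cb, cc, cd = counts
    if cb * cc == 0 or ca * cd == 0:
        raise UndefinedStatisticError(
            f"ROR undefined for counts ({a}, {b}, {c}, {d}) without correction"
        )
    ror = (ca * cd) / (cb * cc)
    se = float(np.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd))
    log_ror = float(np.log(ror))
    return RORResult(
        cancer_type=cancer_type,
        ror=float(ror),
        ci_low=float(np.exp(log_ror - Z_95 * se)),
        ci_high=float(np.exp(log_ror + Z_95 * se)),
        table=table,
        n_reports=int(round(a + b)),
        n_irae=int(round(a)),
        corrected=corrected,
    )


def validate_reports(reports: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPORT_COLUMNS if c not in reports.columns]
    if missing:
        raise InputError(f"report table is missing columns: {missing}")
    if reports["report_id"].duplicated().any():
        raise InputError("report_id values must be unique")
    if (reports["reactions"].map(len) == 0).any():
        raise InputError("every report must list at least one reaction")
    if (reports["indication"].astype(str).str.len() == 0).any():
        raise InputError("every report must carry a cancer-type indication")
    return reports


def filter_monotherapy(
    reports: pd.DataFrame,
    target_drugs: Iterable[str],
    excluded_cotreatments: Iterable[str] = (),
) -> pd.DataFrame:
    """Restrict to reports suspecting a target drug with no excluded co-drug.

    Retains exactly the reports whose suspected-drug set intersects
    ``target_drugs`` and is disjoint from ``excluded_cotreatments`` (e.g.
    dropping anti–PD-1 + ipilimumab combination reports).  Row order is
    preserved and the input frame is untouched.
    """
    targets = frozenset(_normalize_term(d) for d in target_drugs)
    if not targets:
        raise InputError("target_drugs must be nonempty")
    excluded = frozenset(_normalize_term(d) for d in excluded_cotreatments)

    def keep(drugs: Iterable[str]) -> bool:
        normalized = {_normalize_term(d) for d in drugs}
        return bool(normalized & targets) and not (normalized & excluded)

    mask = reports["suspected_drugs"].map(keep)
    return reports.loc[mask].copy()


@dataclass(frozen=True)
class RORScreen:
    """Per-cancer RORs plus the overall case bookkeeping of the stratum."""

    results: tuple[RORResult, ...]
    n_reports: int
    n_irae: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cancer_type": r.cancer_type,
                "n_reports": r.n_reports,
                "n_irae": r.n_irae,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "corrected": r.corrected,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def ror_by_cancer(
    reports: pd.DataFrame,
    terms: IraeTermList,
    correction: str = "haldane",
    comparator_reports: pd.DataFrame | None = None,
) -> RORScreen:
    """Per-cancer-type RORs, comparator = all other cancer types.

    ``comparator_reports`` substitutes a broader stratum (e.g. all reports
    regardless of drug) for the comparator counts; by default the comparator
    is the other cancer types within ``reports`` itself.
    """
    validate_reports(reports)
    is_irae = reports["reactions"].map(lambda rx: terms.matches(rx)).to_numpy()
    types = reports["indication"].to_numpy()
    unique_types = pd.unique(types)
    if len(unique_types) < 2 and comparator_reports is None:
        raise InsufficientGroupsError(
            "at least two cancer types are required to form a comparator"
        )

    if comparator_reports is not None:
        validate_reports(comparator_reports)
        comp_irae = comparator_reports["reactions"].map(terms.matches).to_numpy()
        comp_types = comparator_reports["indication"].to_numpy()
    else:
        comp_irae, comp_types = is_irae, types

    results = []
    for ct in sorted(unique_types):
        index = types == ct
        a = int(np.sum(is_irae & index))
        b = int(np.sum(~is_irae & index))
        comp = comp_types != ct
        c = int(np.sum(comp_irae & comp))
        d = int(np.sum(~comp_irae & comp))
        results.append(ror_from_counts(a, b, c, d, correction=correction, cancer_type=ct))
    return RORScreen(
        results=tuple(results),
        n_reports=int(len(reports)),
        n_irae=int(is_irae.sum()),
    )


def irae_percentage(n_irae: int, n_total: int) -> float:
    """Share of cases with at least one irAE, as a percentage."""
    if n_total <= 0:
        raise DegenerateInputError("total case count must be positive")
    if not 0 <= n_irae <= n_total:
        raise InputError("irAE count must lie between 0 and the total")
    return 100.0 * n_irae / n_total


# ---------------------------------------------------------------------------
# Delimited-text I/O: tab-separated, multi-valued fields semicolon-delimited.

def read_reports(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("suspected_drugs", "reactions"):
        if col not in df.columns:
            raise InputError(f"report file lacks required column {col!r}")
        df[col] = df[col].map(
            lambda s: frozenset(t.strip() for t in s.split(";") if t.strip())
        )
    return validate_reports(df)


def write_reports(reports: pd.DataFrame, path: str | Path) -> None:
    out = reports.copy()
    for col in ("suspected_drugs", "reactions"):
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def make_report_table(
    rows: Sequence[tuple[str, Iterable[str], str, Iterable[str]]],
) -> pd.DataFrame:
    """Build a report table from (id, drugs, indication, reactions) tuples."""
    df = pd.DataFrame(
        {
            "report_id": [r[0] for r in rows],
            "suspected_drugs": [frozenset(r[1]) for r in rows],
            "indication": [r[2] for r in rows],
            "reactions": [frozenset(r[3]) for r in rows],
        }
    )
    return validate_reports(df)
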