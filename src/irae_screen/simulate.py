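"""Synthetic study generator with known planted structure.

Emulates the three data layers of the analysis — spontaneous adverse-event
reports, a pan-cancer molecular cohort, and a patient-level validation
cohort — with every parameter of interest planted and recorded, so that each
downstream stage can be tested for parameter recovery without any external
download.

The planted chain is: per-cancer-type factor means (immune-cell abundances on
the xCell [0, 1] scale, log10 tumor mutational burden) are drawn once; the
true cancer-level ROR is the planted linear combination
``intercept + Σ βⱼ·meanⱼₖ + noise``; the irAE probability of anti–PD-1
monotherapy reports in type k follows from the background odds,
``pₖ = o₀·RORₖ / (1 + o₀·RORₖ)``.  Because the pooled comparator depends on
every stratum, the exact ROR implied for a finite mixture of strata differs
slightly from the nominal planted value; :func:`expected_ror` computes the
exact implied value for convergence tests.

A single global seed feeds a hierarchical stream-splitting scheme
(`numpy.random.SeedSequence.spawn`), so e.g. adding an omics layer never
perturbs the report table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import ExpressionMatrix, compute_tmb
from .validation import CohortTable

# Stream indices of the hierarchical seed split; order is part of the
# determinism contract.
_STREAMS = {"truth": 0, "reports": 1, "patients": 2, "mrna": 3, "mirna": 4,
            "protein": 5, "phosphoprotein": 6, "validation": 7}

#: Default planted weights: the trivariate combination of dendritic-cell
#: abundance, log TMB and naive CD4+ T-cell abundance.
DEFAULT_COEFFICIENTS = {"DC": 19.03, "TMB": 0.82, "naiveCD4T": 18.03}
DEFAULT_INTERCEPT = -1.85

DEFAULT_FACTOR_RANGES = {"TMB": (1.2, 3.2)}
_ABUNDANCE_RANGE = (0.03, 0.15)

_NAMED_MRNA = (
    "PDCD1", "CD274", "GZMA", "PRF1", "IFNG", "STAT1", "IDO1", "CXCL9",
    "CXCL10", "HLA-DRA", "CD3D", "CD3E", "CCL5", "GZMK", "CD2", "CXCL13",
    "IL2RG", "NKG7", "HLA-E", "CXCR6", "LAG3", "TAGAP", "GZMB", "CIITA", "HAVCR2",
    "TIGIT", "CTLA4", "IRF4", "TCL1A", "GPNMB", "FAIM3",
)

_DEFAULT_NON_IRAE_TERMS = (
    "nausea", "fatigue", "headache", "anaemia", "pyrexia", "vomiting",
    "decreased appetite", "dyspnoea", "cough", "constipation", "dizziness",
    "oedema peripheral", "back pain", "insomnia", "pain", "weight decreased",
    "arthralgia bland", "dehydration", "malaise", "fall",
)
_DEFAULT_IRAE_TERMS = (
    "colitis", "pneumonitis", "hypophysitis", "hypothyroidism",
    "hyperthyroidism", "hepatitis", "adrenal insufficiency", "myocarditis",
    "nephritis", "rash maculo-papular", "vitiligo", "uveitis",
    "thyroiditis", "myositis", "encephalitis", "diabetic ketoacidosis",
    "pancreatitis", "guillain-barre syndrome", "pruritus immune",
    "arthritis immune",
)


@dataclass(frozen=True)
class SimConfig:
    """Planted study conditions for the synthetic generator.

    Defaults mirror the scale of the emulated study: 21 cancer types with
    FAERS-like report volumes (~500 eligible reports per type), ~433 patients
    per type (9104/21), and the printed trivariate coefficient set as the
    planted truth.
    """

    n_cancer_types: int = 21
    reports_per_type: int | Sequence[int] = 500
    background_irae_odds: float = 0.16
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = 0.0
    patients_per_type: int = 433
    n_genes: int = 200
    n_mirnas: int = 50
    n_proteins: int = 50
    irae_term_fraction: float = 0.5
    seed: int = 0
    # generator shape parameters
    within_type_sd: float = 0.02
    tmb_within_sd: float = 0.3
    factor_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_RANGES)
    )
    drug_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)  # mono, other, combo
    hit_fraction: float = 0.05
    hit_slope: float = 0.6
    expr_sd: float = 1.0
    min_ror: float = 0.05
    irae_prob_override: float | Mapping[str, float] | None = None
    # validation-cohort parameters
    n_validation_patients: int = 60
    validation_gene: str = "IRF4"
    validation_effect_size: float = 1.0
    validation_irae_fraction: float = 0.5
    n_validation_genes: int = 40

    def __post_init__(self) -> None:
        if self.n_cancer_types < 1:
            raise ConfigError("n_cancer_types must be >= 1")
        rpt = np.atleast_1d(np.asarray(self.reports_per_type))
        if rpt.size not in (1, self.n_cancer_types) or (rpt < 1).any():
            raise ConfigError("reports_per_type must be >= 1 (scalar or per-type)")
        if self.background_irae_odds < 0:
            raise ConfigError("background_irae_odds must be non-negative")
        if self.noise_sd < 0 or self.within_type_sd < 0:
            raise ConfigError("noise/spread standard deviations must be >= 0")
        if self.patients_per_type < 1:
            raise ConfigError("patients_per_type must be >= 1")
        if not 0 <= self.irae_term_fraction <= 1:
            raise ConfigError("irae_term_fraction must lie in [0, 1]")
        if min(self.n_genes, self.n_mirnas, self.n_proteins) < 0:
            raise ConfigError("feature counts must be non-negative")
        if abs(sum(self.drug_mix) - 1.0) > 1e-9 or min(self.drug_mix) < 0:
            raise ConfigError("drug_mix must be a probability vector")
        if not self.true_coefficients:
            raise ConfigError("true_coefficients must name at least one factor")

    @property
    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1:02d}" for i in range(self.n_cancer_types)]

    def reports_vector(self) -> np.ndarray:
        rpt = np.atleast_1d(np.asarray(self.reports_per_type, dtype=int))
        if rpt.size == 1:
            rpt = np.repeat(rpt, self.n_cancer_types)
        return rpt

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass(frozen=True)
class SimTruth:
    """Everything that was planted, for parameter-recovery checks."""

    true_ror: dict[str, float]
    true_irae_prob: dict[str, float]
    planted_factor_means: pd.DataFrame  # cancer types × factors
    true_coefficients: dict[str, float]
    intercept: float
    hit_features: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _quantize_tmb(mean: float) -> float:
    """Snap a planted log10-TMB mean to the integer-count-achievable grid."""
    count = max(int(round(10.0**mean - 1.0)), 0)
    return compute_tmb(count)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the planted per-type factor means and the implied RORs/probs."""
    rng = config.rng("truth")
    types = config.cancer_types
    factors = list(config.true_coefficients)
    means = pd.DataFrame(index=pd.Index(types, name="cancer_type"),
                         columns=factors, dtype=float)
    for f in factors:
        lo, hi = config.factor_ranges.get(f, _ABUNDANCE_RANGE)
        vals = rng.uniform(lo, hi, size=len(types))
        if f == "TMB":
            vals = np.array([_quantize_tmb(v) for v in vals])
        means[f] = vals
    noise = rng.normal(0.0, config.noise_sd, size=len(types)) if config.noise_sd else 0.0
    beta = np.array([config.true_coefficients[f] for f in factors])
    ror = config.intercept + means.to_numpy() @ beta + noise
    ror = np.maximum(ror, config.min_ror)

    o0 = config.background_irae_odds
    if config.irae_prob_override is not None:
        if isinstance(config.irae_prob_override, Mapping):
            prob = np.array([config.irae_prob_override[t] for t in types])
        else:
            prob = np.full(len(types), float(config.irae_prob_override))
        if ((prob < 0) | (prob > 1)).any():
            raise ConfigError("irae_prob_override values must lie in [0, 1]")
        with np.errstate(divide="ignore", invalid="ignore"):
            ror = np.where(
                (prob > 0) & (prob < 1) & (o0 > 0), prob / (1 - prob) / max(o0, 1e-300),
                np.where(prob >= 1, np.inf, 0.0),
            )
    else:
        odds = o0 * ror
        prob = odds / (1.0 + odds)

    return SimTruth(
        true_ror=dict(zip(types, map(float, ror))),
        true_irae_prob=dict(zip(types, map(float, prob))),
        planted_factor_means=means,
        true_coefficients=dict(config.true_coefficients),
        intercept=config.intercept,
    )


def expected_ror(
    probs: Mapping[str, float] | Sequence[float],
    weights: Mapping[str, float] | Sequence[float],
) -> dict[str, float] | np.ndarray:
    """Exact pooled-background ROR implied by planted per-type probabilities.

    For index type k with irAE probability pₖ and expected report weight wₖ,
    the comparator odds pool every other stratum:
    ``RORₖ = [pₖ/(1−pₖ)] / [Σ_{j≠k} wⱼ pⱼ / Σ_{j≠k} wⱼ(1−pⱼ)]``.
    """
    if isinstance(probs, Mapping):
        keys = list(probs)
        p = np.array([probs[k] for k in keys], dtype=float)
        w = np.array([weights[k] for k in keys], dtype=float)
    else:
        keys = None
        p = np.asarray(probs, dtype=float)
        w = np.asarray(weights, dtype=float)
    out = np.empty_like(p)
    for k in range(p.size):
        rest = np.arange(p.size) != k
        comp_odds = np.sum(w[rest] * p[rest]) / np.sum(w[rest] * (1.0 - p[rest]))
        out[k] = (p[k] / (1.0 - p[k])) / comp_odds
    return dict(zip(keys, map(float, out))) if keys is not None else out


def _vocabulary(config: SimConfig) -> tuple[list[str], list[str]]:
    n_irae = int(round(config.irae_term_fraction * 40))
    n_other = 40 - n_irae
    return list(_DEFAULT_IRAE_TERMS[: max(n_irae, 0)]), list(
        _DEFAULT_NON_IRAE_TERMS[: max(n_other, 0)]
    )


def simulate_reports(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate one spontaneous report per row with planted irAE rates.

    Reports carry a cancer-type indication, a suspected-drug set drawn from
    {anti–PD-1 monotherapy, other drug, anti–PD-1 + ipilimumab}, and a
    nonempty reaction-term set.  For monotherapy reports of type k the event
    "at least one irAE term present" occurs with the planted probability.
    """
    truth = simulate_truth(config)
    rng = config.rng("reports")
    irae_terms, other_terms = _vocabulary(config)
    any_prob = any(p > 0 for p in truth.true_irae_prob.values())
    if any_prob and not irae_terms:
        raise ConfigError("irae_term_fraction leaves no irAE term to assign")
    if not other_terms:
        raise ConfigError("reaction vocabulary needs at least one non-irAE term")

    types = config.cancer_types
    counts = config.reports_vector()
    type_idx = np.repeat(np.arange(len(types)), counts)
    n = type_idx.size
    drug_cat = rng.choice(3, size=n, p=np.asarray(config.drug_mix))
    p_vec = np.array([truth.true_irae_prob[t] for t in types])
    o0 = config.background_irae_odds
    p_background = o0 / (1.0 + o0)
    event_p = np.where(drug_cat == 0, p_vec[type_idx], p_background)
    is_irae = rng.random(n) < event_p

    drug_sets = {
        0: frozenset({"nivolumab"}),
        1: frozenset({"other-drug"}),
        2: frozenset({"nivolumab", "ipilimumab"}),
    }
    # Vectorized vocabulary dressing: up to 3 background terms and, for irAE
    # reports, 1-2 irAE terms, drawn with replacement and deduplicated (the
    # event "at least one irAE term present" is exact either way).
    n_other_terms = rng.integers(1, 4, size=n)
    n_irae_terms = rng.integers(1, 3, size=n)
    other_idx = rng.integers(0, len(other_terms), size=(n, 3))
    irae_idx = (
        rng.integers(0, len(irae_terms), size=(n, 2)) if irae_terms else np.zeros((n, 2), int)
    )
    rows_reactions = []
    for i in range(n):
        rx = {other_terms[j] for j in other_idx[i, : n_other_terms[i]]}
        if is_irae[i]:
            rx |= {irae_terms[j] for j in irae_idx[i, : n_irae_terms[i]]}
        rows_reactions.append(frozenset(rx))
    reports = pd.DataFrame(
        {
            "report_id": [f"R{i + 1:07d}" for i in range(n)],
            "suspected_drugs": [drug_sets[int(c)] for c in drug_cat],
            "indication": [types[i] for i in type_idx],
            "reactions": rows_reactions,
        }
    )
    return reports, truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, ExpressionMatrix], SimTruth]:
    """Generate the pan-cancer patient cohort and its omics layers.

    Per-patient factor values are drawn around the planted per-type means
    (within-type spread configurable; zero spread makes per-type medians
    equal the planted means exactly).  Expression values are log-normal;
    a planted subset of features shifts its per-type mean with the true ROR
    (the screen hits), the rest are null.
    """
    truth = simulate_truth(config)
    rng = config.rng("patients")
    types = config.cancer_types
    m = config.patients_per_type
    type_col = np.repeat(types, m)
    n = type_col.size
    patient_ids = [f"P{i + 1:06d}" for i in range(n)]

    data: dict[str, np.ndarray] = {}
    means = truth.planted_factor_means
    for f in means.columns:
        mu = np.repeat(means[f].to_numpy(), m)
        if f == "TMB":
            v = mu if config.within_type_sd == 0 else rng.normal(mu, config.tmb_within_sd)
            counts = np.maximum(np.round(10.0**v - 1.0), 0).astype(int)
            data["nonsynonymous_mutation_count"] = counts
        else:
            v = mu if config.within_type_sd == 0 else rng.normal(mu, config.within_type_sd)
            data[f] = np.clip(v, 0.0, 1.0)

    patients = pd.DataFrame({"patient_id": patient_ids, "cancer_type": type_col, **data})

    ror = np.array([truth.true_ror[t] for t in types])
    z = (ror - ror.mean()) / ror.std() if ror.std() > 0 else np.zeros_like(ror)

    omics: dict[str, ExpressionMatrix] = {}
    hit_features: dict[str, tuple[str, ...]] = {}
    kind_specs = {
        "mrna": (config.n_genes, "G"),
        "mirna": (config.n_mirnas, "miR-"),
        "protein": (config.n_proteins, "PROT-"),
    }
    for kind, (n_feat, prefix) in kind_specs.items():
        if n_feat == 0:
            continue
        krng = config.rng(kind)
        if kind == "mrna":
            named = list(_NAMED_MRNA[: min(len(_NAMED_MRNA), n_feat)])
            fillers = [f"{prefix}{i + 1:05d}" for i in range(n_feat - len(named))]
            feature_ids = named + fillers
            # IRF4 / TCL1A are planted positive hits when present
            planted = [g for g in ("IRF4", "TCL1A") if g in feature_ids]
        elif kind == "protein":
            feature_ids = ["SHC-pY317"] + [f"{prefix}{i + 1:04d}" for i in range(n_feat - 1)]
            planted = ["SHC-pY317"]  # planted negative hit
        else:
            feature_ids = [f"{prefix}{i + 1:04d}" for i in range(n_feat)]
            planted = []
        if config.hit_fraction == 0:
            hits: tuple[str, ...] = ()
        else:
            n_extra = max(int(round(config.hit_fraction * n_feat)) - len(planted), 0)
            # extra hits are drawn from filler features so the named panel
            # genes (signatures, checkpoints) stay null unless planted above
            extra = [
                f for f in feature_ids if f not in planted and f not in _NAMED_MRNA
            ][:n_extra]
            hits = tuple(planted + extra)
        hit_features[kind] = hits

        base = krng.uniform(2.0, 5.0, size=len(feature_ids))
        mu = np.tile(base[:, None], (1, len(types)))  # features × types
        for f_i, fid in enumerate(feature_ids):
            if fid in hits:
                slope = -config.hit_slope if fid == "SHC-pY317" else config.hit_slope
                mu[f_i] = base[f_i] + slope * z
        mu_patient = np.repeat(mu, m, axis=1)  # features × patients
        log2_vals = krng.normal(mu_patient, config.expr_sd)
        values = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)
        omics[kind] = ExpressionMatrix(
            values=pd.DataFrame(values, index=feature_ids, columns=patient_ids),
            kind=kind,
        )

    truth = replace(truth, hit_features=hit_features)
    return patients, omics, truth


def simulate_validation_cohort(config: SimConfig) -> CohortTable:
    """Generate the ICI-treated validation cohort with one shifted gene.

    The designated gene's log2 expression is shifted upward by
    ``validation_effect_size`` in irAE-positive (grade ≥ 1) patients; all
    other genes are null.  Grades among irAE-positive patients follow a
    decreasing severity distribution.
    """
    rng = config.rng("validation")
    n = config.n_validation_patients
    if n < 2:
        raise ConfigError("validation cohort needs at least 2 patients")
    ids = [f"V{i + 1:04d}" for i in range(n)]
    therapy = np.where(rng.random(n) < 0.6, "anti-PD-1", "combination")
    has_irae = rng.random(n) < config.validation_irae_fraction
    grades = np.zeros(n, dtype=int)
    grades[has_irae] = rng.choice(
        [1, 2, 3, 4], size=int(has_irae.sum()), p=[0.4, 0.3, 0.2, 0.1]
    )
    meta = pd.DataFrame(
        {"patient_id": ids, "therapy_class": therapy, "irae_grade": grades}
    )

    named = [config.validation_gene] + [
        g for g in ("IRF4", "TCL1A") if g != config.validation_gene
    ]
    genes = named + [f"VG{i + 1:04d}" for i in range(max(config.n_validation_genes - len(named), 0))]
    base = rng.uniform(1.0, 4.0, size=len(genes))
    log2_vals = rng.normal(np.tile(base[:, None], (1, n)), 1.0)
    shift = np.where(grades >= 1, config.validation_effect_size, 0.0)
    log2_vals[0] = log2_vals[0] + shift
    tpm = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)
    expression = pd.DataFrame(tpm, index=genes, columns=ids)
    return CohortTable(meta=meta, expression=expression)
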