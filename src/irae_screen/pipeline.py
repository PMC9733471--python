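"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` executes (optionally) simulate → ror → features → correlate
→ modelsearch → predict → validate, writes one TSV per stage plus a
machine-readable run summary, and is deterministic under a fixed
configuration: identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, InputError
from .features import FactorMatrix, median_factor_matrix, read_expression, read_gmt
from .models import ExhaustiveModelSearch, predict_external
from .pharmacovigilance import (
    IraeTermList,
    filter_monotherapy,
    irae_percentage,
    read_reports,
    ror_by_cancer,
)
from .screen import screen_factors
from .simulate import SimConfig, simulate_cohort, simulate_reports, simulate_validation_cohort
from .validation import CohortTable, read_cohort, validate_genes, write_cohort

logger = logging.getLogger(__name__)

DEFAULT_SIGNATURE_SCORING = {"CytolyticIndex": "geometric_mean"}


def default_term_file() -> Path:
    return Path(str(resources.files("irae_screen").joinpath("data/irae_terms.txt")))


def default_gmt_file() -> Path:
    return Path(str(resources.files("irae_screen").joinpath("data/signatures.gmt")))


@dataclass
class PipelineConfig:
    """All paths, thresholds and toggles of one pipeline run."""

    out_dir: str = "irae_screen_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_ror: bool = True
    run_features: bool = True
    run_correlate: bool = True
    run_modelsearch: bool = True
    run_predict: bool = False
    run_validate: bool = True
    # thresholds
    fdr_alpha: float = 0.05
    vif_limit: float = 4.0
    lr_alpha: float = 0.05
    pd1_percentile: float = 80.0
    grade_cut: int = 1
    max_model_size: int = 3
    # analysis inputs (used when simulate is off, or to override defaults)
    reports_path: str | None = None
    terms_path: str | None = None
    patients_path: str | None = None
    mrna_path: str | None = None
    mirna_path: str | None = None
    protein_path: str | None = None
    gmt_path: str | None = None
    cohort_meta_path: str | None = None
    cohort_expr_path: str | None = None
    external_medians_path: str | None = None
    target_drugs: tuple[str, ...] = ("nivolumab", "pembrolizumab")
    excluded_cotreatments: tuple[str, ...] = ("ipilimumab",)
    candidates: tuple[str, ...] | None = None
    validation_genes: tuple[str, ...] = ("IRF4", "TCL1A")
    sim: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("fdr_alpha", self.fdr_alpha, 0, 1),
            ("lr_alpha", self.lr_alpha, 0, 1),
            ("pd1_percentile", self.pd1_percentile, 0, 100),
        ):
            if not lo < value < hi:
                raise ConfigError(f"{name} must lie in ({lo}, {hi})")
        if self.vif_limit < 1:
            raise ConfigError("vif_limit must be >= 1")
        if self.grade_cut not in range(1, 5):
            raise ConfigError("grade_cut must lie in 1..4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("target_drugs", "excluded_cotreatments", "candidates", "validation_genes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Fingerprint of the analytic configuration (output path excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        canonical = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sim_config(config: PipelineConfig) -> SimConfig:
    return SimConfig(seed=config.seed, **config.sim)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the toggled stages and return the run-summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "fdr_alpha": config.fdr_alpha,
            "vif_limit": config.vif_limit,
            "lr_alpha": config.lr_alpha,
            "pd1_percentile": config.pd1_percentile,
            "grade_cut": config.grade_cut,
        },
        "stages": {},
    }

    def stage_timer(name):
        start = time.perf_counter()

        def done():
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - start)

        return done

    reports = patients = omics = cohort = truth = None
    if config.simulate:
        done = stage_timer("simulate")
        sim = _sim_config(config)
        try:
            reports, truth = simulate_reports(sim)
            patients, omics, truth = simulate_cohort(sim)
            cohort = simulate_validation_cohort(sim)
        except Exception as exc:
            raise type(exc)(f"stage simulate: {exc}") from exc
        write_cohort(cohort, out_dir / "validation_meta.tsv", out_dir / "validation_expr.tsv")
        summary["stages"]["simulate"] = {
            "n_reports": int(len(reports)),
            "n_patients": int(len(patients)),
            "n_cancer_types": int(sim.n_cancer_types),
        }
        done()
    else:
        if config.run_ror:
            if not config.reports_path:
                raise InputError("stage ror: reports_path required when simulate is off")
            reports = read_reports(config.reports_path)
        if config.run_features:
            if not config.patients_path or not config.mrna_path:
                raise InputError(
                    "stage features: patients_path and mrna_path required when simulate is off"
                )
            patients = pd.read_csv(config.patients_path, sep="\t")
            omics = {"mrna": read_expression(config.mrna_path, "mrna")}
            if config.mirna_path:
                omics["mirna"] = read_expression(config.mirna_path, "mirna")
            if config.protein_path:
                omics["protein"] = read_expression(config.protein_path, "protein")
        if config.run_validate:
            if not config.cohort_meta_path or not config.cohort_expr_path:
                raise InputError(
                    "stage validate: cohort paths required when simulate is off"
                )
            cohort = read_cohort(config.cohort_meta_path, config.cohort_expr_path)

    terms = IraeTermList.from_file(config.terms_path or default_term_file())

    ror_screen = None
    if config.run_ror:
        done = stage_timer("ror")
        if reports is None:
            raise InputError("stage ror: no report table available")
        try:
            mono = filter_monotherapy(
                reports, config.target_drugs, config.excluded_cotreatments
            )
            ror_screen = ror_by_cancer(mono, terms)
        except Exception as exc:
            raise type(exc)(f"stage ror: {exc}") from exc
        ror_screen.to_frame().to_csv(out_dir / "ror.tsv", sep="\t", index=False)
        summary["stages"]["ror"] = {
            "n_monotherapy_cases": ror_screen.n_reports,
            "n_irae_cases": ror_screen.n_irae,
            "irae_percentage": round(
                irae_percentage(ror_screen.n_irae, ror_screen.n_reports), 2
            ),
            "n_cancer_types": len(ror_screen.results),
        }
        done()

    fm: FactorMatrix | None = None
    if config.run_features:
        done = stage_timer("features")
        if patients is None or omics is None:
            raise InputError("stage features: no cohort available")
        if ror_screen is None:
            raise InputError("stage features: ROR stage output missing")
        signatures = read_gmt(
            config.gmt_path or default_gmt_file(), scoring=DEFAULT_SIGNATURE_SCORING
        )
        try:
            fm = median_factor_matrix(
                patients, omics, signatures, ror_screen.results,
                pd1_percentile=config.pd1_percentile,
            )
        except Exception as exc:
            raise type(exc)(f"stage features: {exc}") from exc
        fm.to_frame().to_csv(out_dir / "factors.tsv", sep="\t")
        summary["stages"]["features"] = {
            "n_cancer_types": int(len(fm.cancer_types)),
            "n_factors": int(len(fm.factors)),
        }
        done()

    correlations = None
    if config.run_correlate:
        done = stage_timer("correlate")
        if fm is None:
            raise InputError("stage correlate: factor matrix missing")
        try:
            correlations = screen_factors(fm)
        except Exception as exc:
            raise type(exc)(f"stage correlate: {exc}") from exc
        correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
        panel = correlations[correlations["family"] == "panel"]
        top = correlations.dropna(subset=["r"]).head(5)
        summary["stages"]["correlate"] = {
            "n_factors_tested": int(correlations["p"].notna().sum()),
            "n_panel_significant": int((panel["fdr"] < config.fdr_alpha).sum()),
            "top_factors": [
                {"factor": r.factor, "r": round(r.r, 4), "fdr": round(r.fdr, 6)}
                for r in top.itertuples()
            ],
        }
        done()

    search = None
    if config.run_modelsearch:
        done = stage_timer("modelsearch")
        if fm is None or correlations is None:
            raise InputError("stage modelsearch: correlate stage output missing")
        if config.candidates is not None:
            candidates = list(config.candidates)
        else:
            panel = correlations[correlations["family"] == "panel"]
            significant = panel[panel["fdr"] < config.fdr_alpha]
            if len(significant):
                candidates = sorted(significant["factor"])
            else:
                # no panel factor survives FDR: fall back to the full panel
                logger.warning("no panel factor at FDR < %s; using all", config.fdr_alpha)
                candidates = sorted(panel.dropna(subset=["p"])["factor"])
        if len(candidates) < 1:
            raise InputError("stage modelsearch: no candidate factors")
        try:
            search = ExhaustiveModelSearch(
                candidates=candidates,
                sizes=tuple(range(1, config.max_model_size + 1)),
                vif_limit=config.vif_limit,
                lr_alpha=config.lr_alpha,
            ).fit(fm.values, fm.outcome)
        except Exception as exc:
            raise type(exc)(f"stage modelsearch: {exc}") from exc
        search.results_frame().to_csv(out_dir / "models.tsv", sep="\t", index=False)
        best_by_size = {}
        for size, m in sorted(search.best_by_size_.items()):
            best_by_size[str(size)] = {
                "predictors": list(m.predictors),
                "coefficients": {k: round(v, 6) for k, v in m.coefficients.items()},
                "intercept": round(m.intercept, 6),
                "loocv_r": round(m.loocv_r, 6),
                "unexplained_variance": round(m.unexplained_variance, 6),
                "admissible": bool(m.admissible),
            }
        summary["stages"]["modelsearch"] = {
            "n_candidates": len(candidates),
            "n_models": len(search.results_),
            "best_by_size": best_by_size,
        }
        done()

    if config.run_predict:
        done = stage_timer("predict")
        if search is None:
            raise InputError("stage predict: modelsearch stage output missing")
        if not config.external_medians_path:
            raise InputError("stage predict: external_medians_path required")
        medians = (
            pd.read_csv(config.external_medians_path, sep="\t", index_col=0)
            .iloc[:, 0]
            .to_dict()
        )
        predictions = {}
        for size, m in sorted(search.best_by_size_.items()):
            try:
                predictions[str(size)] = round(predict_external(m, medians), 6)
            except InputError:
                predictions[str(size)] = None
        summary["stages"]["predict"] = {"estimated_ror_by_model_size": predictions}
        done()

    if config.run_validate:
        done = stage_timer("validate")
        if cohort is None:
            raise InputError("stage validate: no validation cohort available")
        try:
            table = validate_genes(
                cohort, config.validation_genes, grade_cut=config.grade_cut
            )
        except Exception as exc:
            raise type(exc)(f"stage validate: {exc}") from exc
        table.to_csv(out_dir / "validation.tsv", sep="\t", index=False)
        summary["stages"]["validate"] = {
            "genes": {
                r.gene: {
                    "median_irae": round(r.median_irae, 4),
                    "median_no_irae": round(r.median_no_irae, 4),
                    "p": round(r.p, 6),
                }
                for r in table.itertuples()
            }
        }
        done()

    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
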