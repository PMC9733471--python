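# irae-screen

Pan-cancer screening of pretreatment biomarkers for immune-related
adverse-event (irAE) risk under anti–PD-1 therapy.

Checkpoint blockade can trigger autoimmune-like toxicities — colitis,
pneumonitis, hypophysitis and other irAEs — and there is no routine
pretreatment marker for who is at risk. This package implements, as a
tested and fully synthetic-data-exercisable pipeline, the integrative
strategy of correlating cancer-level irAE risk estimated from spontaneous
adverse-event reports with cancer-level medians of immunogenomic factors,
then searching exhaustively for small multivariable linear risk models.
It is aimed at biostatisticians and pharmacovigilance/immuno-oncology
analysts who want each statistical step to be inspectable, configurable
and testable against planted ground truth.

## What it computes

**Reporting odds ratio (ROR).** Within the anti–PD-1 monotherapy stratum
(combination therapy with ipilimumab excluded), each report is classified
irAE-positive if at least one reaction preferred term matches a curated
term list. For cancer type *k* versus all other cancer types,

```
ROR_k = (a·d) / (b·c),    95% CI = exp( ln ROR ± 1.96·√(1/a+1/b+1/c+1/d) )
```

with `a/b` the irAE/non-irAE counts of type *k* and `c/d` those of the
comparator. Zero cells get the Haldane–Anscombe +0.5 correction.

**Factor aggregation.** Per patient: TMB = log10(nonsynonymous mutation
count + 1), xCell-style immune-cell enrichment scores, expression-signature
scores (mean of log2(x+1), or geometric mean for the cytolytic index),
checkpoint-gene expression; plus the per-cancer fraction of patients above
the pooled 80th-percentile PD-1 cutoff. Everything except that proportion is
aggregated to per-cancer-type medians, aligned with the ROR outcome vector.

**Correlation screen.** Pearson *r* of each factor median with ROR across
cancer types, two-sided *p* from the *t* reference on *n*−2 df,
Benjamini–Hochberg FDR within each screening family (curated panel;
mRNA / microRNA / protein each separately).

**Model search.** All factor subsets of size 1–3 are fitted by OLS;
performance is the Pearson R between leave-one-cancer-type-out predictions
and the observed ROR (reported with the unexplained variance 1 − R²);
multicollinearity is screened by variance inflation factors (VIF > 4
flags a model) and every model is compared with each nested one-smaller
parent by a Gaussian log-likelihood ratio test (χ² reference). Coefficients
come from the full-data fit; performance from the held-out predictions.

**Cohort validation.** In an independent patient-level cohort (therapy
class, worst CTCAE irAE grade 0–4, gene TPM): Mann–Whitney U between
irAE-positive (grade ≥ 1) and irAE-free patients, a therapy-class-adjusted
logistic regression, and grade-wise comparisons against a reference grade.

A synthetic-data generator plants all of this structure — per-type factor
means, a linear coefficient vector linking them to the true ROR, irAE
probabilities derived from background odds, correlated and null expression
features, and a shifted validation gene — so every stage can be checked for
parameter recovery.

## Worked example

Run the whole pipeline on a simulated study (21 cancer types, 8000 reports
per type, 60 patients per type, planted trivariate truth
ROR = 19.03·DC + 0.82·TMB + 18.03·naiveCD4T − 1.85):

```python
from irae_screen import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="example_run", seed=1,
    candidates=("DC", "TMB", "naiveCD4T"),
    sim=dict(n_cancer_types=21, reports_per_type=8000, patients_per_type=60,
             n_genes=120, n_mirnas=20, n_proteins=20, noise_sd=0.0),
)
summary = run_pipeline(config)
```

The run summary (also written to `example_run/run_summary.json`) contains,
among others:

```
ror:         100294 monotherapy cases, 35339 with >=1 irAE (35.24%)
modelsearch: best by size
  1  naiveCD4T                LOOCV R = 0.539   1-R^2 = 0.710
  2  DC + naiveCD4T           LOOCV R = 0.849   1-R^2 = 0.280
  3  DC + TMB + naiveCD4T     LOOCV R = 0.984   1-R^2 = 0.031  (admissible)
validate:    IRF4 median 16.96 (irAE) vs 5.63 (no irAE), Mann-Whitney p = 2e-05
```

Reading: per-cancer irAE rates pooled to 35.2% of monotherapy cases; the
model search finds that the planted three-factor combination predicts the
estimated RORs far better than any subset (LOOCV R rising 0.54 → 0.85 →
0.98, every nested improvement significant by the likelihood-ratio test and
no VIF above 4); the genome-wide screen ranks the planted expression hits
(IRF4, TCL1A, the negatively-correlated phosphoprotein SHC-pY317) at the
top; and the validation stage recovers the planted IRF4 shift between
irAE-positive and irAE-free patients. The recovered coefficients are
smaller than the planted ones because the pooled-comparator ROR estimated
from reports is a compressed transform of the planted cancer-level values —
see `docs/methods.md`.

The same stages are scriptable from the shell:

```bash
irae-screen simulate --seed 1 --out-dir sim/
irae-screen ror --reports sim/reports.tsv --out ror.tsv
irae-screen features --patients sim/patients.tsv --mrna sim/mrna.tsv \
    --ror ror.tsv --out factors.tsv
irae-screen correlate --factors factors.tsv --out correlations.tsv
irae-screen modelsearch --factors factors.tsv --candidates DC,TMB,naiveCD4T \
    --out models.tsv
irae-screen validate --cohort sim/validation_meta.tsv \
    --expr sim/validation_expr.tsv --genes IRF4,TCL1A --out validation.tsv
```

## Layout

```
src/irae_screen/
  pharmacovigilance.py  report filtering, irAE classification, ROR + CI
  features.py           TMB, signatures, PD-1-high proportion, median matrix
  screen.py             Pearson screen, BH FDR, CorrelationScreen estimator
  models.py             LinearRiskModel, ExhaustiveModelSearch, VIF, LR tests
  validation.py         Mann-Whitney, adjusted logistic, grade comparisons
  simulate.py           planted-structure synthetic study generator
  pipeline.py, cli.py   orchestration, YAML config, irae-screen CLI
docs/methods.md         model assumptions, defaults, numerical choices
tests/                  unit, property and oracle-equivalence suites
```
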