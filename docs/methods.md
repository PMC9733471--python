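# Methods

## Problem and model

The pipeline links two data layers that never meet at the patient level.
Spontaneous adverse-event reports give, per cancer type, a reporting odds
ratio (ROR) for developing at least one immune-related adverse event (irAE)
under anti–PD-1 monotherapy; a molecular cohort gives, per cancer type, the
median of each immunogenomic factor. The working model is linear at the
cancer-type level:

    ROR_k = β0 + Σ_j β_j · median_jk + ε_k

fitted by ordinary least squares over the n cancer types, with predictive
accuracy measured as the Pearson correlation R between
leave-one-cancer-type-out predictions and the observed ROR, and reported
together with the unexplained variance 1 − R². With n around 21, only
small models (one to three factors) are entertained, and each candidate is
additionally screened for multicollinearity and for whether it genuinely
improves on its nested sub-models.

Assumptions worth keeping in mind: the ROR is a disproportionality signal,
not an incidence rate; the linear model treats cancer types as exchangeable
units with homoskedastic residuals; the LOOCV R is computed on the pooled
held-out predictions (not averaged per-fold), which is the natural choice
when every fold predicts a single point.

## Reporting odds ratio stage

The 2×2 table per cancer type is (index type vs all other cancer types) ×
(irAE vs non-irAE), formed inside the anti–PD-1 monotherapy stratum:
reports whose suspected drugs include a target agent and exclude any listed
co-treatment (ipilimumab by default). An alternative comparator stratum can
be supplied explicitly (`comparator_reports`) when the analyst prefers
"all other reports" to "other cancers within the stratum".

- irAE classification is exact preferred-term matching after case-folding
  and whitespace trimming; preferred terms are controlled vocabulary, so no
  fuzzy matching is offered. The shipped term list is a short synthetic
  placeholder; any real analysis must supply its curated, versioned list.
- Wald 95% interval on the log scale with z = 1.959963984540054.
- Zero cells: Haldane–Anscombe +0.5 on all four cells, applied only when
  some cell is zero, and switchable off (`correction="none"` raises on an
  undefined statistic instead of guessing).

## Factor aggregation stage

- TMB = log10(count + 1); base and offset are configurable, and only rescale
  coefficients, not correlations.
- Signature scores: arithmetic mean of log2(x+1) over set genes, or the
  geometric mean exp(mean(ln(x + 0.01))) for the cytolytic index, whose
  conventional pseudocount is 0.01. Set genes missing from the matrix are
  dropped with a warning; a fully absent set is an error, not a NaN.
- Expression preprocessing is fixed as log2(x+1) followed by removal of
  features whose per-cancer-type median is zero in more than half the
  types; medians are taken after the log transform. Both choices are
  documented here because the upstream convention is not standardized.
- "PD-1-high" uses the pooled linear-interpolation percentile (default
  80th) and counts patients *strictly* above it, which keeps the
  all-values-equal case well defined (proportion 0 everywhere).
- All factors except the PD-1-high proportion are per-cancer medians
  (pandas convention: midpoint for even groups).

## Correlation screen

Pearson r with a two-sided p from the t reference on n−2 df; constant
vectors are reported as excluded results with a reason rather than silent
NaNs, and are removed from the FDR multiplicity. Benjamini–Hochberg is
applied within screening families — the curated panel as one family, each
omics kind as its own — because a hand-picked panel of ~10 factors and a
genome-wide screen of thousands should not share a multiplicity budget.
The family map is configurable.

## Model search

All subsets of the candidate factors of sizes 1..K (default K = 3) are
fitted. Per model:

- Full-data OLS coefficients and the Gaussian maximum-likelihood
  log-likelihood ℓ = −(n/2)(ln(2π σ̂²) + 1), σ̂² = RSS/n. An exact fit
  (RSS = 0) floors σ̂² at 1e-12 and sets a degenerate-fit flag instead of
  producing an infinite log-likelihood.
- LOOCV predictions through the exact leverage identity
  ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ), which the test suite verifies against an
  explicit per-fold refit to 1e-10. A leverage of 1 (singular fold) raises
  a fold-failure error naming the fold.
- VIF_j = 1/(1 − R²_j) from regressing predictor j on the others with
  intercept; exact collinearity reports an infinite VIF rather than raising.
- A likelihood-ratio test Λ = 2(ℓ_full − ℓ_reduced) against χ² with the
  coefficient-count difference as df, run against *every* one-smaller
  parent subset (size-1 models test against the intercept-only model).

A model is *admissible* when all parent LR tests have p < 0.05 and no VIF
exceeds 4 (both thresholds configurable). BH adjustment of the LOOCV-R
p-values is performed within each model-size family. Ranking is by LOOCV R
descending with deterministic tie-breaks (fewer predictors, then
lexicographic predictor names). Reported coefficients are always the
full-data fit; external predictions apply those coefficients to supplied
factor medians.

A property worth knowing when reading LOOCV R values: for an uninformative
model the held-out predictions anti-correlate with the outcome, so pure
noise yields markedly *negative* R (around −0.4 at these n), not zero.
Chance-level models therefore never look optimistic.

## Cohort validation

irAE occurrence is binarized at grade ≥ 1 (configurable). Mann–Whitney U
(U = Σ [a > b] + ½[a = b] over cross pairs) uses the exact distribution
when n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. The therapy-adjusted
association is a maximum-likelihood logistic regression of occurrence on
expression plus a therapy-class indicator; the indicator is dropped when
only one class is present, a rank-deficient design (expression confounded
with therapy) raises a diagnostic, and non-convergence or runaway
coefficients (|β| > 50, the signature of complete separation) raise a
convergence error rather than returning meaningless Wald statistics.
Grade-wise comparisons test each grade group against a reference grade
(default 4). No multiplicity correction is applied across validation genes
by default, matching the usual practice of reporting nominal p in a small
confirmatory panel; `bh_adjust` is available.

## Synthetic-data generator

The generator's defaults mirror the scale of the emulated study design:
21 cancer types, roughly 500 eligible reports and 433 cohort patients per
type, a background irAE odds of 0.16 (which puts pooled irAE frequencies
near 30% of monotherapy cases for RORs in the 1–6 range), and the reported
trivariate coefficient set (19.03·DC + 0.82·TMB + 18.03·naiveCD4T − 1.85)
as the planted linear truth. Abundance-type factor means are drawn
uniformly on [0.03, 0.15] and log-TMB means on [1.2, 3.2]; these ranges
keep the planted linear combination positive while spanning a realistic
ROR spread.

Chain of planted quantities:

1. Per-type factor means → true ROR via the planted linear model (+
   optional cancer-level Gaussian noise, floored at 0.05 to keep the odds
   construction valid). TMB means are snapped to the grid
   log10(round(10^m − 1) + 1) achievable by integer mutation counts, so
   the zero-spread case reproduces planted means *exactly*.
2. True irAE probability p_k = o₀·ROR_k / (1 + o₀·ROR_k) with background
   odds o₀; non-monotherapy reports use the background probability
   o₀/(1 + o₀). A probability override exists for boundary cases (planted
   probability exactly 0 or 1).
3. Reports: indication, drug category (monotherapy / other / combination
   mixture), and a reaction set that contains at least one irAE term with
   probability p_k for monotherapy reports. The irAE-term event is exact;
   the particular terms drawn are cosmetic dressing.
4. Cohort: per-patient factor values around the planted means (normal,
   configurable spread; abundances clipped to [0, 1]); expression values
   are log-normal (2^N(μ, σ) − 1, floored at 0) to resemble TPM. A planted
   fraction of features (including named positives IRF4/TCL1A and the
   negative phosphoprotein SHC-pY317) shifts its per-type mean linearly
   with the standardized true ROR; all other features, including the named
   signature and checkpoint genes, are null.
5. Validation cohort: 60 patients, two therapy classes, grades 0–4 with a
   decreasing severity profile among irAE-positive patients, and one
   designated gene shifted on the log2 scale by a configurable effect size.

Because the pooled comparator depends on every stratum, the ROR estimated
from reports is a *compressed*, slightly nonlinear transform of the nominal
planted value; `expected_ror` computes the exact implied value, and
convergence tests compare against it, not the nominal number. This is also
why end-to-end coefficient estimates are attenuated relative to the planted
β while the recovered *predictor set* is stable.

A single global seed feeds a fixed-order `SeedSequence.spawn` split, one
stream per table, so adding an omics layer never perturbs the report table
and identical configurations give byte-identical outputs.

What the generator does **not** emulate: report duplication and reporting
bias, indication misclassification, within-type covariance structure
between factors, batch effects or dropout in expression data, and any
survival/exposure-time process. Passing tests therefore demonstrate
statistical correctness of the machinery and recoverability of planted
structure, not robustness to those real-data pathologies.

## Problem sizes used in the test and acceptance runs

The deep suites run at sizes chosen to make their statistical assertions
sharp while completing in minutes on one CPU: 200 random report tables for
the brute-force ROR equivalence; 20 000 reports per type for ROR
convergence (3 asymptotic SEs); 50 random fixtures for the LOOCV identities
(1e-10); 100 Monte-Carlo replicates for noisy coefficient recovery (3 SEs
of the replicate mean); 200 replicates × 1000 features for BH calibration;
and every group-size pair with n₁·n₂ ≤ 36 for exact Mann–Whitney
enumeration.

## Known limitations

- The ROR stage deliberately implements no report deduplication and no
  disproportionality statistic beyond the ROR (no PRR/EBGM).
- The comparator construction ("other cancers within the stratum") is one
  of two defensible readings; the alternative is available but not the
  default.
- FDR family definitions (panel vs per-omics, per-model-size) are design
  choices exposed as configuration, not facts about the data.
- Cancer-level regression cannot support patient-level risk statements;
  the validation stage exists precisely because of that gap.
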