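# Methods

This note records the statistical model, the algorithmic and numerical
choices, and what the synthetic-data experiments do and do not
establish.

## Phenotype derivation

A progression phenotype is defined by a pair of code sets: baseline
diagnoses (3-character ICD-10 prefixes, e.g. `E78`) and outcome
diagnoses or procedures (ICD-10 prefixes or exact OPCS-4 strings, e.g.
`K451`). Per person, `t0` is the age at the earliest baseline event and
`t1` the age at the earliest outcome event on or before the censoring
date; without an outcome, follow-up ends at death or the censoring
date, whichever is earlier, with status 0 (death is censoring, not an
event). Persons whose earliest outcome is **at or before** `t0` are
excluded — "prior to" is read strictly, which also guarantees `y = t1 −
t0 > 0`. The derivation partitions the cohort exhaustively into
included / excluded-by-ordering / no-baseline, and the counts are
reported.

Dates of birth are reconstructed from month and year of birth as the
first day of the birth month. Registry sentinel dates receive fixed
corrections before any age is computed: 1902-02-02 → DOB, 1903-03-03 →
DOB + 6 months, 2037-07-07 and 1900-01-01 removed. Events within
[DOB − 31 days, DOB) are moved to the DOB; the 31-day window is a
deliberate convention, since a calendar-month match is ambiguous across
month lengths. Non-sentinel events more than 31 days before birth
cannot yield a valid age and are removed (counted separately). Ages are
days/365.25; an age of exactly zero is recorded as 1/12 year because
the survival model requires strictly positive times. Cleaning is
idempotent for cohorts born after the sentinel era (all modern
biobanks); a pathological DOB in 1901–1903 could alias a corrected date
back onto a sentinel, which we accept rather than complicate the rules.

Case thresholds (strictly more than 15,000 baseline individuals and
400 outcome events by default) are a screen for analyzable phenotypes;
they are configurable and scaled down in the demo pipeline.

## Genotype handling

PLINK 1 BED/BIM/FAM is the canonical backing format (variant-major
2-bit codes; the codec is implemented here bit-exactly and round-trip
tested). Dosages count the BIM A1 allele. QC keeps variants with
missing rate ≤ 10% and MAF ≥ 0.001 (both bounds inclusive), computed on
the full cohort *before* splitting — as in standard array
preprocessing — while imputation means and standardization are computed
on the **training split only**, so no information from validation or
test individuals leaks into the model scale. Missing calls are imputed
with the per-variant training mean (the convention of the sparse
whole-genome regression software family this package follows; the
choice matters little at the missing rates QC admits). Variants
monomorphic in the training split are dropped. Column batches (default
1,000 columns) bound peak memory at `n_rows × batch_size` doubles, and
batched reads are bit-identical to single-shot reads.

## The solver

The partial likelihood uses the **Breslow** tie convention throughout —
the convention of the lasso-Cox literature, cheap at scale, and exactly
matched by the reference implementations used in the tests
(scikit-survival, statsmodels PHReg). The objective is the negative
**mean** partial log-likelihood plus λ‖β_pen‖₁; the 1/n scaling makes λ
comparable across sample sizes and fixes the meaning of λ_max = max_j
|∂(ℓ/n)/∂β_j| at the covariate-only optimum. Adjustment covariates are
never penalized.

`fit_penalized` is proximal Newton: at the current linear predictor η
the Breslow score residuals u and diagonal curvatures h are computed in
O(n) via cumulative risk-set sums, and the resulting weighted-lasso
surrogate is solved by cyclic coordinate descent (numba kernel,
active-set sweeps) with soft-thresholding. Numerical safeguards, each
load-bearing:

* **All columns are centered inside the solver.** The partial
  likelihood is location-invariant, so the constant direction is a null
  direction of the true Hessian, but the diagonal surrogate assigns it
  curvature — for an uncentered covariate like age (~55) the surrogate
  overestimates single-coordinate curvature ~3,000-fold and the
  iteration crawls. Centering changes no coefficient, likelihood or
  gradient value.
* The surrogate is solved to a weighted-squared-change tolerance of
  `(10·tol)²/10`, tied to the outer KKT target; convergence is declared
  only when the relative objective change is below `tol` (default
  1e-7) **and** the subgradient conditions hold within `10·tol`.
* Steps are halved when the surrogate overshoots the true objective, so
  the objective is non-increasing across iterations.
* η is clipped at ±500 before exponentiation (with a warning); IRLS
  weights are floored at 1e-5.

Near path saturation (active set approaching the event count) the
partial likelihood approaches quasi-separation and any first-order
method crawls; like the rest of the glmnet family, the path is
stopped by validation performance long before this regime.

`fit_cox_newton` is a conventional Newton–Raphson with the full
observed information (risk-set cumulative sums, step halving), used for
covariate-only fits and for the low-dimensional evaluation models where
Wald standard errors are needed.

## BASIL

The path runs over `n_lambda` (default 100) log-spaced penalties from
λ_max down to λ_max/100. The candidate subset starts as the
`batch_screen_size` variants with the largest null-model score and only
ever grows. After each subset solve, the full-data score at the
solution is streamed in column batches; excluded variants violating
|g_j| ≤ λ + kkt_tol trigger screening of the strongest excluded
variants (all violators included) and a re-solve of the same λ, so
**every reported λ satisfies full-variant-set KKT** — this is also
verified independently in the tests, not just by the fitter's own
bookkeeping. `max_basil_iter` (default 50) caps screening
augmentations; exhausting it returns the verified partial path with a
warning.

Model selection maximizes the validation C-index of the **full** linear
predictor (variants + covariates); the genotype-only C-index is logged
alongside. Rationale: selection should reflect total fit quality, while
the score reported downstream is polygenic by definition
(variant-only). Ties break toward the larger λ (sparser model). The
path stops after `early_stop_patience` (default 2) consecutive λ
without improving the best validation C-index.

The 70/10/20 train/validation/test split is a uniform random partition
(sizes rounded per fraction), reproducible from `split_seed`; splits
with zero events are rejected.

## Evaluation

* **C-index**: Harrell's concordance over comparable pairs — i has an
  event strictly before y_j; tied scores count 1/2; pairs tied in time
  or censored-before-event are incomparable. Verified against exact
  brute-force enumeration including heavy ties.
* **Scale HR**: Cox fit on phs/SD(phs) alone (Breslow, Newton), Wald
  p-value and 95% CI. Unadjusted by default — the minimal reading of
  single-number progression PHS reports — with `adjusted=True` adding
  the standard covariates. Wald rather than likelihood-ratio inference:
  the convention of large-cohort PHS reporting; at these n the
  difference is negligible.
* **Percentile HRs**: groups by within-cohort percentile rank (top1 >
  0.99 ⊂ top5 > 0.95 ⊂ top10 > 0.90; bottom10 ≤ 0.10; reference
  (0.40, 0.60]), each extreme vs the reference in a two-group Cox
  model. Percentile boundaries are computed on the evaluation cohort
  itself; rank ties break by stable person-id order for determinism.
  Empty or event-free comparisons are reported as unavailable (blank
  cells), not errors.
* **Kaplan–Meier**: product-limit curves per group (lifelines backend),
  with censoring tick marks and cumulative incidence 1 − S(t) at fixed
  horizons (default 1, 10, 15, 22 years).
* Evaluation cohorts must be disjoint from training individuals
  (checked by person id); an all-constant PHS (possible when the null
  model wins on null data) yields a report with undefined HR fields
  rather than a failure.

## Synthetic data

The generator emulates what the analysis assumes: independent biallelic
variants at MAFs uniform on a configured range (no LD — the pipeline is
LD-agnostic and recovery tests are cleaner without it; real-data
support recovery is harder because LD spreads signal across correlated
variants), completely-at-random missingness, a sparse causal
architecture on the per-SD scale, and event times that are exponential
given the linear predictor (proportional hazards with constant baseline
hazard). Censoring times are exponential with the rate calibrated by
bisection so the expected censored fraction hits the target (realized
fractions land within ±0.02 at the sample sizes used). An optional
granularity flag rounds times up to a grid to inject heavy ties
(ages-in-months data are heavily tied). Covariate effects default to
0.03/year of baseline age (centered at 55) and 0.25 for sex, modest
values of the order seen in cardiometabolic progression; PCs and array
carry no effect.

Standing simulation conditions used by the tests and the acceptance
script, chosen once as desk-scale analogues of a biobank progression
analysis: n = 4,000 individuals, p = 2,000 variants, 15 causal variants
with per-SD effects of magnitude 0.1–0.3, baseline hazard 0.05/year,
30% censoring (null calibration uses n = 1,000, p = 500, no causal
variants; solver-agreement instances use n = 500, p = 200). The mock
EHR generator injects controlled quotas of each sentinel-date anomaly
on filler-code records so cleaning reports can be asserted
record-for-record.

What passing these tests shows: the solver solves the problem it
claims (full-data KKT, agreement with independent references), the
metrics are exact, and under the generator's assumptions the pipeline
recovers sparse architectures and is calibrated under the null. What
they do not show: robustness to LD, population structure, relatedness,
informative censoring, imputation dosage uncertainty, or code-mapping
noise in real EHR data — all outside the generator by design.

## Known limitations

* Breslow only; no Efron correction, time-varying covariates,
  stratified baselines, or elastic-net mixing.
* The EHR pipeline stage fits the genotype-linked simulated phenotype;
  the derived-from-EHR phenotype demonstrates the cleaning/derivation
  contract (the mock event tables are not coupled to the genotypes).
* Coordinate descent is not suited to the near-saturated end of the
  path (quasi-separation); rely on validation-based early stopping, as
  the defaults do.
* The CI-coverage check for the per-SD hazard ratio uses the *true*
  simulated predictor, because the "true" per-SD effect of an
  *estimated* score is not a well-defined simulation parameter.
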