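# Methods

`synthqc` validates a synthetic ("virtual cohort") version of a tabular
clinical dataset against the real dataset it imitates. This note documents
the statistical procedures, the choices made where the design was open, and
what the bundled fixture generator does and does not emulate.

## Data model

A cohort is a rectangular table of mixed numeric and categorical variables
with first-class missing cells (never numeric sentinels): clinical extracts
carry heavy structured missingness — e.g. a whole CSF panel absent for a
participant — and a sentinel encoding would contaminate every downstream
moment. Numeric variables may carry assay-censored raw strings (`">1,700"`,
`"<200"`) until preprocessing resolves them. Schemas are serialized as a
JSON sidecar next to each CSV so that round-trips preserve types exactly.

## Preprocessing

Four rules map a raw extract to the analysis schema:

1. **Censored values.** `">x"` maps to x+1 and `"<x"` to x−1 (1701 and 199
   for the CSF ABeta(1-42) detection limits of 1,700 and 200 pg/ml) — a
   conventional just-outside-the-range encoding that keeps the column
   numeric without discarding censored records.
2. **BMI** = weight (kg) / (height (cm) / 100)². Height is treated as
   centimeters: a cohort mean height of 166.7 is only plausible in cm.
3. **Amyloid positivity**: 1 when ABeta(1-42) < 1,000 pg/ml, strictly — the
   boundary value 1,000 is negative, matching the flag's definition as
   "abeta < 1,000". (Published descriptions of this flag's 0/1 coding are
   sometimes internally inconsistent; this package fixes 1 = positive.)
4. **Family history**: 1 when a *biological* father or mother had a history
   of dementia; a parent with missing answers is non-contributing.

## Fidelity metrics

- **KS (numeric)**: asymptotic two-sample Kolmogorov–Smirnov p-value on
  non-missing values. High p (> 0.05 by convention) means the marginals are
  indistinguishable. The asymptotic rather than exact p-value is used; at
  cohort sizes in the hundreds-to-thousands the difference is negligible.
- **KL (categorical)**: KL(real ‖ synthetic) in nats — the information lost
  when the synthetic level distribution approximates the real one. This
  direction is fixed by that interpretation. Reported both raw (plug-in;
  infinite when the synthetic data misses an observed level) and with
  add-0.5 smoothing over the union of observed levels.
- **PCD-L1**: the correlation matrices of both cohorts (Pearson,
  pairwise-complete) are compared entrywise; PCD-L1 is the **mean** absolute
  difference over the strict upper triangle. The mean (not the sum) is used
  so the value reads as an average per-pair discrepancy independent of the
  variable count; a sum variant is available behind `reduce="sum"`.
  Categorical variables enter as 0/1 indicators — binary variables as a
  single indicator, multi-level ones as leave-one-out indicators with the
  pooled most-frequent level dropped so both cohorts share reference levels.
- **Discriminator AUC**: a LightGBM classifier is trained to separate real
  (label 0) from synthetic (label 1) records; AUC is computed on pooled
  out-of-fold probabilities from stratified 5-fold CV, repeated 10 times
  with seeds derived from one master seed. 0.5 means indistinguishable.
  Byte-identical encoded rows are constrained to the same fold
  (`StratifiedGroupKFold`): otherwise an exact duplicate with the opposite
  label on the training side of the split lets the learner memorize and
  anti-predict, driving the AUC of a *perfect* copy toward 0 instead of the
  correct 0.5. For cohorts without cross-label duplicates the grouping is a
  no-op. Missing values go to the tree learner natively.
- **UMAP coverage**: a UMAP model (n_neighbors=50, min_dist=0.1) is fitted
  on the real cohort only and both cohorts are projected through it
  (deterministic transform). The bounding box of the real points is split
  into a 20×20 grid; coverage is the fraction of cells containing a real
  point that also contain a synthetic point. This grid quantification is
  this package's own device for the usual visual cluster-coverage check,
  and the report labels it as such. Inputs are median-imputed and
  standardized with real-cohort statistics so no variable dominates the
  embedding by scale.
- **Descriptive comparison**: per-variable Welch t-tests (numeric) and
  two-proportion z-tests (per categorical level), missing dropped,
  degenerate comparisons reported as undefined rather than raised.

## Utility metrics

A binary outcome (default: amyloid positivity) is predicted from covariates
that exclude the outcome's source variable and anything derived from it
(default roster: age, sex, education years, BMI, family history, ApoE
genotype, RBANS total). Two learners are compared — LightGBM and logistic
regression (median-impute + standardize pipeline) — each evaluated by
stratified 5-fold CV with pooled out-of-fold AUC, repeated 10 times with
derived seeds, within the real and within the synthetic cohort. No
hyperparameter tuning is performed by default: fixed, sensible learner
settings keep the protocol deterministic and the real-vs-synthetic contrast
clean.

Feature importance is the mean absolute Shapley value per feature from the
GBT model fit on the full cohort, computed with LightGBM's built-in TreeSHAP
(`pred_contrib=True`), sorted descending with ties broken by name. Ranking
agreement between the real-trained and synthetic-trained models uses nDCG
with graded relevance equal to the real model's mean |SHAP|:
DCG(order) = Σᵢ rel(fᵢ)/log₂(i+1) (1-based), nDCG = DCG(candidate)/DCG(reference),
in (0, 1], and 1 exactly when the orders agree up to relevance ties.

## Privacy: distance to closest record

Numeric variables are discretized into 25 equal-width bins over the pooled
(real ∪ synthetic) non-missing range — pooled edges guarantee the two
cohorts are binned identically; quantile binning is available behind a flag.
MISSING is its own category and matches itself (matching missingness
patterns is genuinely similarity; an always-mismatch variant is behind a
flag). The record distance is the number of differing positions (integer
Hamming). For every synthetic record the distance to the closest real record
is computed exhaustively, and for every real record the distance to the
closest *other* real record; the summary statistic is
mean(syn→real) / mean(real→real). Near 1: synthetic records are no closer to
the real data than the real data is to itself. Near 0: memorization. If the
real data itself contains binned duplicates the denominator is 0 and the
ratio is reported as undefined with a warning.

## Baseline synthesizer

The bundled generator is a Gaussian copula with empirical marginals: numeric
columns are rank-transformed to normal scores (average ranks at ties),
categorical columns enter through uniform jitter within their level's
cumulative-frequency band, and a binary missingness indicator per
incompletely-observed variable joins the copula so block-missing patterns
are part of the dependence structure. The latent correlation matrix is
estimated pairwise-complete and repaired to positive semi-definiteness by
clipping eigenvalues at 10⁻⁶ and renormalizing the diagonal. Sampling draws
a latent multivariate normal and inverts through empirical quantiles
(linear interpolation) and level thresholds. It is a deliberately simple,
fully transparent baseline — adequate for exercising the validation suite
end to end, and making no claim of parity with proprietary generation
engines (its discriminator AUC on the bundled fixture is around 0.72, i.e.
clearly detectable, while its marginals, pairwise correlations and
missingness rates are reproduced well).

## Fixture generator

`generate_epad_like` emits a raw preclinical-dementia-style cohort whose
marginal means/sds, level frequencies and missingness rates default to the
published descriptive table of a deeply phenotyped n=1,498 sample: age
truncated at 50, height/weight (correlation 0.5, invented), CSF p-tau/t-tau
(correlation 0.9, invented), ABeta(1-42) with detection-limit censoring
rendered as raw strings, ApoE genotype frequencies, parental-history raw
columns consistent with a 61.6% family-history rate, and a shared
missingness indicator for the CSF panel. BMI is deliberately not
precomputed so preprocessing has real work to do.

Two calibration choices matter:

- **Truncated normals.** For age (≥ 50) and education (≥ 0) the generator
  solves for the underlying (loc, scale) whose *post-truncation* mean and sd
  equal the published targets; naive truncation of N(65.6, 7.2) at 50 would
  inflate the realized mean by ≈ 0.28 years, which is detectable at large n.
- **Planted amyloid signal.** ABeta decreases by 150 pg/ml per ApoE-e4
  allele and 5 pg/ml per year of age over 50. The effect is centered and its
  variance subtracted from the noise budget, so the marginal keeps its
  configured mean/sd while the amyloid-positivity outcome becomes learnable
  from genotype and age (population AUC of the generating score ≈ 0.60).

What the fixture does **not** emulate: real longitudinal structure, real
inter-assay correlations (the invented latent correlations are labeled
configurable defaults), non-Gaussian marginal shapes, and informative
missingness beyond the block-CSF pattern. Passing tests on fixtures
therefore demonstrate that the metrics behave correctly — identities,
oracle equivalence, defect detection, parameter recovery — not that any
particular real synthetic-data product is faithful.

`generate_toy_pair` supplies four ground-truth defect scenarios (identical,
one-sd mean shift, column-wise permutation, row memorization) used to show
each metric moves when and only when its defect is present.

## Numerical and protocol choices

- Master seed → per-module seeds via `numpy.random.SeedSequence`; every
  derived seed is recorded in the report.
- All learners run single-threaded (`n_jobs=1`) for determinism.
- Problem sizes in the test suite: identity checks at n=1,498 (the reference
  cohort size), oracle checks at n ≤ 200, recovery checks at n=10,000 to
  100,000 — chosen so each check's sampling error is far below its tolerance.
- Degenerate inputs: zero-variance variables are excluded from correlation
  matrices (logged), zero-range variables collapse to one bin (logged), an
  undefined sd or p-value is reported as NaN rather than raised, and an
  all-missing column is an error naming the column.

## Known limitations

- The discriminator and utility protocols fix one reasonable CV design;
  other designs (train-on-synthetic/test-on-real, tuned learners) would give
  different absolute numbers. The package exposes seeds and settings rather
  than claiming protocol-free values.
- UMAP coverage depends on the grid size and on UMAP's own stochasticity
  across library versions; it is a reproducible summary of a visual check,
  not a calibrated statistic.
- DCR is a nearest-neighbor heuristic; it is not a formal membership-
  inference or differential-privacy guarantee.
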