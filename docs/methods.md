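# Methods

`prsmr` implements a one-sample Mendelian randomization (MR) analysis in
which a polygenic risk score (PRS) for a circulating biomarker —
adiponectin, measured in ng/ml and analyzed as Z-standardized natural-log
values — instruments the biomarker's causal effect on nine cardiometabolic
outcomes: HOMA-IR, HDL, LDL, total cholesterol, triglycerides, SBP, DBP
(continuous, per-SD), and T2D and hypertension (binary, odds ratios).
This note records the models, the defaults and why, and what the synthetic
testbed does and does not establish.

## Study design being modelled

Two data sources: *base* GWAS summary statistics for log-adiponectin from an
external meta-analysis (default N = 29,347, standardized-trait scale), and a
*target* case-control cohort with genotypes, the measured exposure, outcomes
and covariates. The instrument is built by clumping + thresholding (C+T) in
the target data, which also serves as its own LD reference. Because no
public individual-level cohort exists for this design, the package ships a
generator that produces both sources with known ground truth; every
statistical claim the test suite makes is a claim about estimator behaviour
under that generator.

## Synthetic data generator

**Genotypes.** Variants come in LD blocks spread over the 22 autosomes,
separated by > 1 Mb so LD never crosses a clumping window. Within a block
all variants share one minor-allele frequency and each haplotype copies its
previous allele with probability `s`, else redraws it; this makes the
adjacent-genotype correlation exactly `s`, so `s = sqrt(target_adjacent_r2)`
calibrates the block LD with no tuning. We chose this copy process over a
thresholded latent Gaussian because the calibration is exact and the cost is
O(n·m); the analysis only needs LD strong enough to make clumping
non-trivial, not a realistic human LD map. Population structure follows a
Balding–Nichols model (default 3 subpopulations, Fst = 0.02) so principal
components have real signal; genotype missingness is injected at 0.5% so
call-rate filters and mean-imputation scoring have work to do.

**Exposure.** Standardized log-exposure
`X = G·b + γx·U + ε` with `U ~ N(0,1)` a shared unobserved confounder.
The per-allele effects `b` load on one SNP per block (default 50 blocks) and
are rescaled so that together they explain `instrument_variance_fraction`
(default 0.03) of var(X); that fraction is a design choice pinned to give a
first-stage F in the tens at n ≈ 2000, the regime the design targets.
The biomarker in natural units is `exp(8.93 + X)` ng/ml, matching a median
near 7.5·10³ ng/ml with a wide log-normal spread.

**Outcomes.** Each continuous outcome has a latent
`Z = β_causal·X + sign·γy·U + covariate effects (+ pleiotropy) + noise`
mapped to natural units (e.g. LDL = 132 + 35·Z mg/dl); the confounder's
sign per outcome is negative for HOMA-IR, triglycerides and T2D and
positive elsewhere, so the *observational* associations reproduce the
familiar direction pattern even where the causal effect is zero. The default
causal architecture is a single positive effect on LDL (β = 0.55 per SD) and
null effects elsewhere. T2D is made consistent with its diagnostic rule: a
logistic latent sets case probability, glucose is then drawn conditional on
case status (≥ 7.0 mmol/L for unmedicated cases), and T2D is re-derived as
`glucose ≥ 7.0 mmol/L or glucose-lowering medication`. HOMA-IR is computed
as insulin·glucose/22.5 from simulated log-normal insulin and the same
glucose, so the rule "exclude T2D cases from HOMA-IR analyses" has bite.
Hypertension is derived, not drawn: `SBP ≥ 130 or DBP ≥ 80 or BP
medication`. Case-control ascertainment oversamples T2D cases from a 3×
pool until the cohort case share hits `case_fraction` (default 0.48).

**What the generator does not emulate:** realistic human LD decay and
haplotype sharing, imputation error structure (INFO is drawn uniform on
[0.3, 1] purely to exercise the filter), sex chromosomes, genotyping-batch
effects, and non-random phenotype missingness. Passing tests therefore
establish correctness of the *estimators and pipeline mechanics* under a
known structural model — not robustness to every pathology of real cohort
data.

## QC stack

Filter order is fixed and recorded in the report: marker missingness
(> 0.01) → MAF (< 0.01) → Hardy–Weinberg exact test (p < 1e−6) → INFO
(< 0.8), then sample missingness (> 0.01) → heterozygosity F beyond 3 SD of
the cohort mean → relatedness. Marker metrics must precede sample metrics;
within each group the order follows convention. The HWE test is the exact
conditional test computed by a mode-anchored ratio recurrence (numerically
safe at any n; validated against full rational-arithmetic enumeration for
every configuration with ≤ 50 genotypes). Harmonization drops duplicated
ids and palindromic (A/T, C/G) variants unconditionally — no
frequency-based rescue — resolves strand mismatches by complementing, and
flips the effect-allele sign when the base effect allele aligns to the
target's other allele.

Kinship uses the KING-robust between-family estimator
`φ = (N_het,het − 2·N_opp-hom)/(N_het,i + N_het,j)`; pairs above the
second-degree cutoff 0.0884 are resolved greedily (most-flagged member
first; ties by call rate, then id). With a few hundred retained variants the
estimator's null spread widens and a small number of false flags is
expected; the pruning is deliberately conservative. PCs come from a
randomized SVD of the column-standardized, mean-imputed dosage matrix;
missing dosages are imputed only for the PCA.

## Score construction

Clumping is greedy by ascending p (ties: position, then id) with defaults
r² > 0.1 within 250 kb — widely used C+T settings. The p-value cutoff is
chosen from a grid (default {5e−8 … 1} of 11 points; a log-spaced fine grid
is available) to maximize the score's incremental R² over a covariate-only
regression of the exposure; ties favour the smaller cutoff. Missing dosages
score as twice the effect-allele frequency of the non-missing samples.

The empirical p-value permutes the exposure (10,000 times at study scale;
1000 in the bundled fixture to keep a desk run under a minute) and re-runs
the entire grid optimization per permutation, via the projected-residual
identity: with Q an orthonormal basis of [1, C] and s̃ the score
residualized on Q, the incremental R² equals (s̃'ỹ)²/(s̃'s̃·SStot). This is
algebraically the same number the two-regression refit produces (a test
asserts equality to 1e−12) and reduces each permutation to a handful of dot
products.

## Causal estimators

All estimators use the PRS as a single instrument `z` for the standardized
log-exposure `x`, with adjustment sets *partial* (age, sex, PC1–3) and
*full* (+ BMI, alcohol, smoking); SBP/DBP models additionally adjust for BP
medication. Standardization is computed on each outcome's full analysis
sample *before* stratification, so stratum estimates stay on one per-SD
scale.

* **2SLS** is solved as just-identified IV: θ = (Z'W)⁻¹Z'y with
  W = [x, 1, C], Z = [z, 1, C]. The SE uses structural residuals
  y − β̂x − γ̂'C (not second-stage residuals). For a single instrument the
  slope equals the covariate-residualized Wald ratio cov(z̃,ỹ)/cov(z̃,x̃);
  a test asserts this identity to 1e−10.
* **GMM (continuous)** shares the point estimate with 2SLS (just-identified
  algebra) and differs only in its heteroskedasticity-robust sandwich SE
  V = G⁻¹SG⁻ᵀ/n with S = Σ zᵢzᵢ'ûᵢ².
* **Binary two-stage** fits the exposure linearly on z + C over all samples
  (cases and controls; the ascertainment caveat is probed by the simulator's
  case-control design), then a logistic regression of the outcome on the
  fitted exposure + C. Model-based SEs are the default; a nonparametric
  bootstrap over individuals (default 1000 resamples) is available because
  two-stage model SEs understate uncertainty.
* **GMM (binary)** solves E[(y − expit(α + βx + γ'C))·(1, z, C')'] = 0 by
  Newton iteration from the naive logistic start, with covariate and
  instrument columns standardized internally (the β on x is invariant to
  that affine reparametrization; without it the moment components are on
  wildly different scales and line searches stall). A hybrid root-finder is
  the fallback; a "root" reached with a saturated linear predictor
  (|η| > 30) is reported as non-convergence — that is separation, not a
  solution. A logistic structural mean is one reading of the two-step
  binary GMM; a multiplicative-mean variant would be a straightforward
  extension but is not implemented.

First-stage strength is reported crude and adjusted as F = t²; estimates
with F ≤ 10 carry a weak-instrument flag and warning. Strata are all /
BMI < 25 / BMI ≥ 25 / men / women; sex strata drop sex from the covariates;
an empty or degenerate stratum is reported as unavailable with the reason,
never silently skipped.

**Sensitivity checks.** Confounder balance regresses the score on each of
age, sex, BMI, alcohol and smoking separately, with no multiplicity
adjustment. The pleiotropy scatter computes per-SNP PC-adjusted regressions
of exposure and outcome on dosage (an ordinary linear model; the synthetic
cohort has no hidden relatedness after QC, so a mixed model would add
nothing here), fits an inverse-variance-weighted through-origin line of
SNP-outcome on SNP-exposure effects, and flags points whose residual
exceeds 3 in studentized units, where the studentization propagates both
axes' standard errors (|b_y − slope·b_x| / sqrt(se_y² + slope²·se_x²)).
The threshold formalizes what is usually a visual check and is configurable.

## Observational layer

Linear models for Z-standardized continuous outcomes (HOMA-IR and
triglycerides natural-log-transformed first) and logistic models for the
binary ones, per 1 SD of standardized log-exposure, under the same
adjustment sets and exclusions (lipid-medication users excluded everywhere;
T2D cases excluded for HOMA-IR). Descriptive tables summarize normally
distributed variables as mean (95% Wald CI) with t-tests, skewed variables
(adiponectin, HOMA-IR, TG) as median (25th–75th pct) with Mann–Whitney U,
and categoricals as percent (95% Wald CI) with chi-square tests. Wald
intervals are the default for proportions (z = 1.96); they are simple,
match the reporting convention this design follows, and are exact enough at
these cell sizes.

## Numerical choices and degenerate inputs

* Clumping tie-break: p, then position, then id — fully deterministic.
* Threshold tie-break: smaller cutoff wins.
* `ld_r2` uses pairwise-complete entries and raises on zero variance.
* Monomorphic SNPs are dropped from the scatter with a warning.
* All randomness flows from one seed through per-stage substreams; the same
  config + seed reproduces estimate tables byte-for-byte.
* Bed codec: PLINK1 variant-major two-bit encoding with NaN for the missing
  code; round-trips exactly.

## Problem sizes used in the checks

The bundled end-to-end fixture runs n = 2000 samples × m = 5000 variants
with 1000 permutations (≈ 20–30 s on one core). Estimator-calibration
studies use a direct structural-equation draw (`simulate_iv_dataset`) —
instrument explaining 5–8% of exposure variance, confounder loading 0.4 on
both exposure and outcome — at n = 1000–2000 over 200–1000 replicates;
these sizes give Monte-Carlo error comfortably inside the asserted bands.
Under those conditions 2SLS shows |bias| ≤ 0.05 where OLS is biased by
≈ 0.16, 95% CI coverage within [91%, 98%], and type-I error within
[3.6%, 6.4%].

## Known limitations

* The LD model has constant within-block MAF and geometric-decay r²; there
  is no inter-block admixture LD.
* The binary two-stage estimator inherits the usual caveats of two-stage
  methods under case-control ascertainment; the simulator can probe this
  (raise `case_fraction` against a rarer population prevalence) but the
  package does not correct for it.
* MR-Egger, weighted-median and multivariable MR are out of scope: the
  design's instrument is a single score, and per-SNP instruments in the
  target population are too weak to support them.
* Proportion CIs are Wald; exact binomial intervals are available through
  scipy if a caller needs them, but are not wired into the tables.
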