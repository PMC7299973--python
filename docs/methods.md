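# Methods

This note documents the models implemented in `snpsurv`, the assumptions
behind the synthetic-cohort generator, the numerical choices in the
solvers, and the limits of what passing tests demonstrate.

## Synthetic cohorts

The generator emulates the statistical structure of a germline-SNP
pharmacogenomics study in metastatic colorectal cancer, where the real
patient-level data are under restricted access.

**Genotypes.** Each SNP is specified by a minor allele frequency
m ∈ [0, 0.5]. SNPs outside an LD block are drawn as two independent
Bernoulli(m) alleles per patient, so genotype frequencies are
(1−m)², 2m(1−m), m² in expectation — Hardy-Weinberg equilibrium by
construction. LD blocks are specified as explicit haplotype pools
(haplotype vector → frequency); each patient draws two haplotypes, which
produces co-inheritance with any desired D′/r, including perfect LD.
Block marginals must agree with the per-SNP MAF to 1e-6 or the
configuration is rejected. Missingness is completely at random at a
configurable rate, matching the coverage-style filters of the analysis,
which imply no informative-missingness model.

**Covariates.** Sex (60/40), age (normal, mean 63, sd 10, clipped to
25–90 years), and KRAS status (wt/mutant/unknown at 47/37/16%) — the
frequencies of a first-line metastatic colorectal cancer population.

**Survival.** Progression-free survival is exponential with rate
`baseline_hazard × exp(linear predictor)`; the linear predictor sums the
planted SNP effects (additive, dominant or recessive coding, each with a
log hazard ratio) and any covariate effects (numeric covariates centred).
Censoring is the minimum of an independent exponential draw and an
administrative cut-off. Overall survival is the latent relapse time plus
an exponential residual sharing the same linear predictor, so OS ≥ PFS
holds by construction and SNP effects act on both endpoints.

Defaults (units: rates per day, times in days): baseline hazard
log 2 / 300 (median PFS ≈ 300 days ≈ 10 months at null), censoring rate
1/1500 (light random drop-out), administrative censoring 1095 days (3
years); OS residual hazard log 2 / 450 (median OS ≈ 750 days ≈ 25 months)
with a 1825-day (5-year) cut-off. These match a first-line
bevacizumab + chemotherapy setting: ~80% PFS event rate within follow-up.
Exponential baselines were chosen for closed-form checks (the event
fraction under exponential event/censoring competition is h/(h+c), which
the tests verify); a Weibull option is not needed for any property tested
and was left out of scope.

Seeding: one master seed per cohort; genotypes, covariates and survival
use master + 0/1/2; stability-selection repeat r uses master + r for both
the subsample draw and the fold split, making results reproducible and
independent of scheduling.

Because effect sizes are not identifiable from published summaries, the
planted log hazard ratios are free parameters of the simulator — recovery
tests demonstrate that the pipeline finds effects of the planted
magnitude at the simulated cohort size, not that any particular real SNP
has that effect.

## Quality control

Discovery inclusion requires, per SNP: carrier frequency (non-missing
patients with ≥1 minor allele) in [0.10, 1.00) — inclusive below,
exclusive at 100%; reference-population MAF ≥ 0.05 (a SNP absent from the
reference table fails); call rate ≥ 0.90; and a unique gene annotation.
Carrier frequency uses non-missing patients as the denominator (the
alternative, all patients, is a configurable choice). Validation cohorts
require call rate ≥ 0.80 only.

The Hardy-Weinberg test is the standard exact conditional test: given the
allele counts, the probability of every heterozygote count is computed
(log-gamma arithmetic, normalised in place) and the p-value sums those no
more probable than the observed one. Monomorphic samples give p = 1. The
1-df chi-square approximation agrees with the exact test only
asymptotically; at n ≈ 2000 the two can differ by ~0.05 in the mid-p
range, so the agreement test uses n = 50,000 grids. HWE filtering is
applied to the candidate set after selection (matching the analysis
workflow), with the operation also exposed for pre-filtering; the rule is
p strictly greater than 1e-4.

## Survival machinery

`cox_fit` maximises the partial likelihood by Newton-Raphson with
step-halving (relative slack 1e-10 absorbs rounding near the optimum).
Ties: Efron by default — the convention of reporting models — and Breslow
optionally, which is also what the penalized solver uses internally; the
two coincide exactly on tie-free data. Convergence requires max |score|
< 1e-9 (or a 1e-10 relative log-likelihood change with score already
below 1e-8); the covariance is the inverse observed information.
Constant and collinear-to-tolerance (smallest singular value < 1e-8 of
the largest) columns are rejected. A coefficient path exceeding |β| > 15
is treated as monotone likelihood (perfect separation) and flagged
non-converged rather than returned silently — the score vanishes
numerically along such a ridge, so the score criterion alone cannot
detect it. Stratified fits sum per-stratum likelihood contributions
(separate baseline hazards, shared coefficients); pooled multi-cohort
analyses stratify by cohort as the conservative choice.

The log-rank test is computed from at-risk/event counts on the shared
event-time grid and is vectorised over batches of group-label vectors;
this is what makes 10,000-permutation corrections cheap. The corrected
p-value is the plain frequency #{p_b ≤ p_obs}/B (an add-one-smoothed
variant is available); since permutation preserves group counts, the df
is constant and the comparison is done on the chi-square statistics.

Genotype association fits genotype encoding(s) plus covariates on
complete cases (dummy coding, first level as reference; exclusion counts
logged). The across-genotype Wald test has 2 df for the codominant model
and 1 df otherwise. Empty genotype groups yield a flagged inestimable
record. "Dominant" and "recessive" refer to the minor allele; groupings
relative to the major allele (e.g. "any major-allele carrier") are
expressed with the `flip` flag on `encode`.

## Penalized Cox solver

The elastic-net path follows the glmnet design: predictors standardised
internally to zero mean and unit population (1/N) variance, penalty
`λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` applied on the standardised scale, coefficients
reported on the original scale; λ_max = max_j |score_j(0)|/(nα) (the
smallest λ with an all-zero KKT-feasible solution), then a log-spaced
descending grid (default 100 values down to 0.05·λ_max when P > N, else
0.01·λ_max). Pure ridge (α = 0) has no finite λ_max and is unsupported.

Each λ is warm-started. An outer IRLS iteration builds the quadratic
approximation to the Breslow partial likelihood (per-patient working
weights floored at 1e-10), cyclic coordinate descent with
soft-thresholding solves it on the active set, and a full KKT sweep with
the true partial-likelihood score re-activates any violating predictor
before the solution is accepted — so every reported solution passes a
complete KKT audit. Step-halving enforces a non-increasing penalised
objective; an objective increase beyond 1e-10 aborts with diagnostics,
and an iteration cap without convergence is flagged on the path. Paths
stop early once the active set exceeds `dfmax` (default: the number of
patients) or the deviance ratio saturates (> 0.999 or per-λ gain
< 1e-5) — near-saturated fits are unidentifiable and carry no selection
information. Default tolerances (coordinate step 1e-7 weighted, outer
1e-7) are chosen for path work; the λ→0 equivalence check against the
unpenalized Newton fit uses 1e-9 and agrees to ~1e-6.

Cross-validation uses seeded permutation folds (sizes within 1), shares
the full-data λ grid across folds, scores each λ by the
Verweij–Van Houwelingen deviance −2·[ll(all; β_fold) − ll(train; β_fold)]
summed per fold, and reads the nonzero set at λ_min off the full-data
path. Folds with event-free training sets are redrawn (bounded retries).

Genotypes enter the penalized model as additive dosages with
mean-imputation of missing calls (preserves allele frequency); clinical
covariates are not part of the selection model, though unpenalized
columns are supported (`penalty_free_idx`).

## Stability selection

Each repeat draws ⌊0.9·N⌋ patients without replacement, recomputes the λ
grid on the subsample (λ_max is data-dependent), runs 3-fold CV and
counts the λ_min nonzero set. Thresholds follow the two aggregation
rules: LASSO strict > 25% of repeats, elastic net ≥ 70%. For subsample
repeats the path uses 50 λ values, a 0.05 floor ratio and dfmax = 30:
at desk-scale cohorts (N ≈ 180) the CV deviance minimum sits at a handful
of predictors, so the deeper, denser tail adds computation but no
selection signal — these are the package's choices for repeat-scale work,
and the full-resolution path remains the default everywhere else.
Repeats whose subsample cannot support three folds with events are
skipped and logged (more than 5% skips is an error).

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotype
pairs by EM: all genotype pairs except the double heterozygote decompose
uniquely; the double heterozygote is split between the two phases by the
current odds f11·f00 / (f11·f00 + f10·f01). Initialisation at linkage
equilibrium; convergence at 1e-10 maximum frequency change. The
likelihood surface for two loci is unimodal in this parameterisation, so
restarts are unnecessary. D = f11 − p1·p2, D′ = |D|/D_max with the usual
frequency-dependent bound, r = D/√(p1q1p2q2). Monomorphic SNPs (in the
jointly non-missing subset) are an error — LD is undefined.

## Two-SNP combination

The three-group labelling gives SNP1 minor-homozygotes their own group
regardless of SNP2, then SNP2 minor-homozygotes, then the baseline
(≥1 major allele at each locus); a missing call at a deciding SNP leaves
the patient unassigned. Whether a SNP1 homozygote with missing SNP2
should be assignable is not determined by the design being emulated; the
precedence rule makes it assignable, which is the choice documented here.
The group model fits two indicators against baseline plus covariates,
with KM curves and a log-rank test across groups.

## Prediction error curves

The Brier score at t uses Graf weights: events before t weighted
1/G(T⁻), patients at risk past t weighted 1/G(t), patients censored
before t contributing zero, with G the Kaplan-Meier estimate of the
censoring distribution. G = 0 where a weight is needed raises a
truncation error. With no censoring the score reduces exactly to the
mean squared error of survival status against prediction. Curves compare
models by ordinary out-of-bag bootstrap (default B = 100): fit on the
in-bag draw, score on the disjoint out-of-bag set, average over
resamples; the .632 variant was not implemented because the comparisons
of interest are ordinal (which model predicts better), not absolute.
The null model predicts the in-bag marginal KM survival for everyone.

## Problem sizes in the test suite

Simulation-backed tests state their sizes explicitly: stability-selection
recovery uses 50 replicate cohorts of N = 180 patients × P = 500 SNPs
with 200 repeats each; CI coverage uses 500 cohorts of n = 2000;
permutation-null calibration uses 200 replicates at B = 500. These sizes
give Monte-Carlo error small enough for the stated bounds (e.g. binomial
SE ≈ 1% at 500 replicates for a 95% coverage check) and are the package's
standard verification scale. `scripts/acceptance.py` runs a 10-replicate
version of the stability suite and reports the recovery fraction it
computes.

## What passing tests do and do not show

The generator draws independent patients, exponential hazards, completely
random missingness and at most block-local LD. Real cohorts have
population structure, genotyping batch effects, informative censoring,
non-proportional hazards and genome-wide LD, none of which are simulated.
Passing the recovery and calibration suites therefore validates the
implementation of the statistics — not the clinical claims of any
particular study, and not robustness to the violations above. Known
limitations: no imputed dosages or multiallelic sites; no
time-varying covariates or frailty terms; contingency enumeration capped
at 3×3 tables; no ridge-only penalized path.
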