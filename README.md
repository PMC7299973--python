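# snpsurv

Germline SNP biomarker discovery for survival outcomes, as used in
pharmacogenomic studies of bevacizumab + chemotherapy in metastatic
colorectal cancer: SNP quality control, repeated cross-validated penalized
Cox stability selection, covariate-adjusted genotype association,
permutation-corrected testing, linkage disequilibrium, two-SNP combination
analysis, and prediction-error-curve model evaluation — exercised
end-to-end on synthetic cohorts with known ground truth.

The package is aimed at biostatisticians who want a tested, reproducible
reimplementation of this analysis style: every statistical primitive (the
Hardy-Weinberg exact test, the elastic-net Cox coordinate-descent solver,
the IPCW Brier score, two-locus EM linkage disequilibrium) is implemented
in-package and audited against independent oracles, and a synthetic-cohort
generator stands in for restricted patient-level data.

## The statistics at the core

**Penalized Cox selection.** For genotype dosages `x_i ∈ {0,1,2}^P` and
right-censored times, the solver maximises the Breslow partial likelihood
penalised by `λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)` via cyclic coordinate descent on
the IRLS quadratic approximation, with a warm-started descending λ path
and 3-fold cross-validation scored by the Verweij–Van Houwelingen
cross-validated partial-likelihood deviance. α = 1 is the LASSO; α = 0.5
is the elastic net used for discovery.

**Stability selection.** The cross-validated selection at λ_min is
repeated over random 90% patient subsets (default 1000 repeats); SNPs
selected in more than 25% of LASSO repeats or at least 70% of elastic-net
repeats form the candidate set, post-filtered for Hardy-Weinberg
departures (exact conditional test, p > 1e-4 required).

**Association and validation.** Candidates are tested in multivariable Cox
models (Newton–Raphson, Efron ties) under codominant / dominant /
recessive codings with across-genotype Wald tests, Kaplan-Meier/log-rank
summaries with a permutation-based multiplicity correction (10,000
genotype permutations), Fisher exact genotype-distribution comparisons
between cohorts, and pairwise D′/r from unphased genotypes via EM.

**Model evaluation.** Competing models are compared by bootstrapped
out-of-bag prediction error curves: the IPCW Brier score
`BS(t) = n⁻¹ Σ w_i(t) (1{T_i > t} − Ŝ(t|x_i))²` with Graf weights from the
censoring Kaplan-Meier estimate, followed over a time grid.

## Worked example

```python
import numpy as np
from snpsurv import (SNPSpec, EffectSpec, simulate_cohort,
                     run_stability, genotype_association)

# a 180-patient cohort with one planted dominant effect (HR 2.5) at MAF 0.3
specs = [SNPSpec("planted", 0.3)] + [SNPSpec(f"noise{j}", 0.25) for j in range(99)]
gm, clinical = simulate_cohort(
    180, specs, [EffectSpec("planted", "dominant", np.log(2.5))], seed=7)

profile = run_stability(gm, clinical, alpha=0.5, n_repeats=200, master_seed=1)
print(f"planted selection frequency: {profile.frequency()[0]:.2f}")
print(f"median noise frequency:      {np.median(profile.frequency()[1:]):.2f}")

rec = genotype_association(gm, "planted", "dominant", clinical, ["sex", "age"])
hr, (lo, hi) = rec.hazard_ratios[0], (rec.ci_lower[0], rec.ci_upper[0])
print(f"adjusted HR {hr:.2f} (95% CI {lo:.2f}-{hi:.2f}), Wald p {rec.wald_p:.4f}")
```

prints

```
planted selection frequency: 0.92
median noise frequency:      0.00
adjusted HR 2.63 (95% CI 1.86-3.72), Wald p 0.0000
```

— the planted SNP is selected in 92% of stability repeats (far above the
70% elastic-net threshold) while noise SNPs are almost never selected, and
the adjusted Cox model recovers the planted hazard ratio with a confidence
interval covering the truth.

The same analysis runs from the shell through a YAML config:

```sh
snpsurv simulate --config config.yaml
snpsurv discover --config config.yaml   # QC -> stability -> candidates -> Cox scan
snpsurv evaluate --config config.yaml   # prediction error curves
```

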