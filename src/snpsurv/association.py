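"""Candidate validation statistics.

Covers the post-selection statistics applied to candidate SNPs: adjusted
Cox scans across genetic models, permutation-corrected log-rank tests,
Fisher exact and chi-square contingency tests for genotype and cohort
characteristic tables, pairwise linkage disequilibrium (D, D', r) from
unphased genotypes by EM, and the two-SNP combined-genotype analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from scipy.stats import chi2_contingency as _scipy_chi2

from .io import ClinicalTable, GenotypeMatrix
from .survival import (
    AssociationRecord,
    SurvivalCurve,
    _logrank_stats_batch,
    build_design,
    cox_fit,
    genotype_association,
    km,
    logrank,
)

__all__ = [
    "COVARIATE_PRESETS",
    "LDStats",
    "CombinedGroupResult",
    "adjusted_scan",
    "permutation_corrected_logrank",
    "fisher_exact_rxc",
    "chisq_contingency",
    "genotype_distribution_fisher",
    "ld_pair",
    "two_snp_groups",
    "combined_group_association",
]

#: Cohort-specific covariate adjustment sets (column names in the clinical
#: table).  The discovery cohort adjusts for sex, age, grade, chemotherapy
#: line, backbone and BRAF; the two validation cohorts use their own sets;
#: synthetic cohorts carry sex and age.
COVARIATE_PRESETS: dict[str, list[str]] = {
    "APD": ["sex", "age", "grade", "chemo_line", "backbone", "braf"],
    "MAVERICC": ["age", "ecog", "n_metastases", "resection"],
    "TRIBE": ["age", "sex", "ecog", "primary_site", "resection",
              "liver_limited", "adjuvant", "braf", "ras"],
    "SIM": ["sex", "age"],
}


def _resolve_covariates(preset, clinical: ClinicalTable) -> list[str]:
    if isinstance(preset, str):
        cols = COVARIATE_PRESETS[preset]
    else:
        cols = list(preset)
    return [c for c in cols if c in clinical.data.columns]


# ---------------------------------------------------------------------------
# Adjusted Cox scan
# ---------------------------------------------------------------------------

def adjusted_scan(
    candidates: list[str],
    gm: GenotypeMatrix,
    clinical: ClinicalTable,
    covariate_preset="SIM",
    endpoint: str = "pfs",
    models: tuple[str, ...] = ("codominant", "dominant", "recessive"),
    subgroup: tuple[str, object] | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """One adjusted association row per candidate SNP x genetic model.

    ``subgroup`` restricts to patients where a clinical column equals a
    value (e.g. ``("kras", "wt")``).  Inestimable fits (monomorphic SNP in
    the subgroup, empty genotype group) are flagged in the output rather
    than dropped.
    """
    if not candidates:
        raise ValueError("no candidate SNPs to scan")
    if subgroup is not None:
        col, val = subgroup
        keep = np.flatnonzero((clinical.data[col] == val).to_numpy())
        gm = gm.subset(patient_idx=keep)
        clinical = ClinicalTable(clinical.data.iloc[keep])
    covariates = _resolve_covariates(covariate_preset, clinical)
    rows = []
    for snp_id in candidates:
        for model in models:
            rec: AssociationRecord = genotype_association(
                gm, snp_id, model, clinical, covariates, endpoint, ties=ties
            )
            rows.append(rec.to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation-corrected log-rank
# ---------------------------------------------------------------------------

def permutation_corrected_logrank(
    gm: GenotypeMatrix,
    snp_id: str,
    clinical: ClinicalTable,
    endpoint: str = "pfs",
    B: int = 10000,
    seed: int = 0,
    smoothed: bool = False,
    chunk: int = 1000,
) -> tuple[float, float]:
    """Raw and multiple-testing-corrected log-rank p for one SNP.

    The corrected p-value is the frequency of permutations of the genotype
    vector (survival data fixed) achieving a log-rank p at or below the
    observed one; with genotype group counts preserved under permutation
    the df is constant, so the comparison is done on the chi-square
    statistics.  ``smoothed`` uses the add-one estimate (1 + #)/(1 + B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    g = gm.column(snp_id)
    time, event = clinical.endpoint(endpoint)
    keep = ~np.isnan(g)
    g, time, event = g[keep], time[keep], event[keep]
    levels, codes = np.unique(g, return_inverse=True)
    if levels.size < 2:
        raise ValueError(f"{snp_id}: genotype forms a single group; log-rank undefined")
    n_groups = levels.size
    df = n_groups - 1
    stat_obs = float(_logrank_stats_batch(time, event, codes[:, None], n_groups)[0])
    raw_p = float(chi2.sf(stat_obs, df))

    rng = np.random.default_rng(seed)
    n_extreme = 0
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perm = rng.permuted(np.tile(codes, (b, 1)), axis=1).T  # (n, b)
        stats = _logrank_stats_batch(time, event, perm, n_groups)
        n_extreme += int((stats >= stat_obs - 1e-12).sum())
        done += b
    corrected = (1 + n_extreme) / (1 + B) if smoothed else n_extreme / B
    return raw_p, float(corrected)


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

_MAX_FISHER_TABLES = 5_000_000


def fisher_exact_rxc(table) -> float:
    """Exact conditional independence test for a small r x c count table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (two-sided by probability ordering; exact hypergeometric for 2 x 2).
    Tables whose enumeration would exceed an internal work bound raise an
    unsupported-table error.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if t.shape[0] > t.shape[1]:
        t = t.T
    r, c = t.shape
    if r > 3 or c > 3:
        raise ValueError(f"enumeration unsupported for {r}x{c} tables")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    lg = gammaln(np.arange(n + 2))
    const = float(lg[row + 1].sum() + lg[col + 1].sum() - lg[n + 1])
    obs_ll = const - float(lg[t + 1].sum())
    total = 0.0
    count = 0

    # enumerate tables row by row; the last row is fixed by the column margins
    def rec(i: int, rem_col: list[int], ll_acc: float) -> None:
        nonlocal total, count
        if i == r - 1:
            ll = const + ll_acc - sum(lg[x + 1] for x in rem_col)
            count += 1
            if count > _MAX_FISHER_TABLES:
                raise ValueError("table too large for exact enumeration")
            if ll <= obs_ll + 1e-7:
                total += np.exp(ll)
            return

        cells: list[int] = []

        def fill(j: int, rem_row: int) -> None:
            if j == c - 1:
                if rem_row > rem_col[j]:
                    return
                cells.append(rem_row)
                new_rem = [rem_col[k] - cells[k] for k in range(c)]
                ll = -sum(lg[x + 1] for x in cells)
                rec(i + 1, new_rem, ll_acc + ll)
                cells.pop()
                return
            for v in range(min(rem_row, rem_col[j]) + 1):
                cells.append(v)
                fill(j + 1, rem_row - v)
                cells.pop()

        fill(0, int(row[i]))

    rec(0, [int(x) for x in col], 0.0)
    return float(min(total, 1.0))


def chisq_contingency(table, yates_for_2x2: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square independence test, Yates-corrected for 2 x 2.

    Returns ``(statistic, df, p)`` with df = (r - 1)(c - 1); a zero row or
    column margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero margin in contingency table")
    correction = yates_for_2x2 and t.shape == (2, 2)
    res = _scipy_chi2(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def genotype_distribution_fisher(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix, snp_id: str
) -> float:
    """Fisher exact p comparing a SNP's genotype counts between two cohorts."""
    ca = gm_a.genotype_counts(snp_id)
    cb = gm_b.genotype_counts(snp_id)
    table = np.array([ca, cb]).T  # genotypes x cohorts
    table = table[table.sum(axis=1) > 0]
    return fisher_exact_rxc(table)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDStats:
    """Two-locus LD summary from EM haplotype frequencies.

    ``haplotype_freqs`` keys are (allele at SNP1, allele at SNP2) with 1 =
    minor allele.  D is the deviation of the minor/minor haplotype from
    independence, D' its value scaled to the maximum attainable given the
    allele frequencies, r the haplotype correlation.
    """

    haplotype_freqs: dict[tuple[int, int], float]
    D: float
    D_prime: float
    r: float
    n_iter: int
    loglik: float
    n_used: int


def ld_pair(gm: GenotypeMatrix, snp1: str, snp2: str, tol: float = 1e-10,
            max_iter: int = 5000) -> LDStats:
    """Pairwise LD from unphased genotypes via the two-locus EM algorithm.

    Starts from linkage-equilibrium haplotype frequencies and iterates the
    double-heterozygote phase split until the largest frequency change is
    below ``tol``.  Requires both SNPs polymorphic among patients
    non-missing at both.
    """
    g1 = gm.column(snp1)
    g2 = gm.column(snp2)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    n = g1.size
    if n < 2:
        raise ValueError("fewer than 2 patients non-missing at both SNPs")
    p1 = g1.mean() / 2
    p2 = g2.mean() / 2
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    n_dh = counts[1, 1]

    # fixed haplotype contributions from unambiguous genotypes
    base = np.zeros((2, 2))  # [allele1][allele2] counts
    for a in range(3):
        for b in range(3):
            if (a, b) == (1, 1):
                continue
            c = counts[a, b]
            if c == 0:
                continue
            # each non-double-het genotype decomposes into two haplotypes
            alle1 = [1, 1] if a == 2 else ([1, 0] if a == 1 else [0, 0])
            alle2 = [1, 1] if b == 2 else ([1, 0] if b == 1 else [0, 0])
            # for single-het genotypes the pairing is unambiguous
            base[alle1[0], alle2[0]] += c
            base[alle1[1], alle2[1]] += c

    f = np.array([[(1 - p1) * (1 - p2), (1 - p1) * p2], [p1 * (1 - p2), p1 * p2]])
    it = 0
    for it in range(1, max_iter + 1):
        denom = f[1, 1] * f[0, 0] + f[1, 0] * f[0, 1]
        q = 0.5 if denom == 0 else f[1, 1] * f[0, 0] / denom
        new = base.copy()
        new[1, 1] += q * n_dh
        new[0, 0] += q * n_dh
        new[1, 0] += (1 - q) * n_dh
        new[0, 1] += (1 - q) * n_dh
        new /= 2.0 * n
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new

    D = f[1, 1] - p1 * p2
    if D >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = 0.0 if dmax == 0 else abs(D) / dmax
    r = D / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    # observed-data log-likelihood at the EM solution
    ll = 0.0
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0:
                continue
            if (a, b) == (1, 1):
                prob = 2 * (f[1, 1] * f[0, 0] + f[1, 0] * f[0, 1])
            else:
                alle1 = [1, 1] if a == 2 else ([1, 0] if a == 1 else [0, 0])
                alle2 = [1, 1] if b == 2 else ([1, 0] if b == 1 else [0, 0])
                prob = f[alle1[0], alle2[0]] * f[alle1[1], alle2[1]]
                if (alle1[0], alle2[0]) != (alle1[1], alle2[1]):
                    prob *= 2
            ll += c * np.log(max(prob, 1e-300))
    freqs = {
        (1, 1): float(f[1, 1]), (1, 0): float(f[1, 0]),
        (0, 1): float(f[0, 1]), (0, 0): float(f[0, 0]),
    }
    return LDStats(freqs, float(D), float(d_prime), float(r), it, float(ll), n)


# ---------------------------------------------------------------------------
# Two-SNP combined genotype analysis
# ---------------------------------------------------------------------------

GROUP_BASELINE = "baseline"
GROUP_SNP1_HOM = "snp1_hom_minor"
GROUP_SNP2_HOM = "snp2_hom_minor"
GROUP_UNASSIGNED = "unassigned"


def two_snp_groups(gm: GenotypeMatrix, snp1_id: str, snp2_id: str) -> np.ndarray:
    """Three-group combined genotype labels with SNP1-homozygote precedence.

    A patient homozygous for the minor allele at SNP1 is labelled
    ``snp1_hom_minor`` regardless of SNP2; otherwise a minor homozygote at
    SNP2 is ``snp2_hom_minor``; everyone else (at least one major allele
    at each SNP) is ``baseline``.  Missing calls at a deciding SNP give
    ``unassigned``.
    """
    g1 = gm.column(snp1_id)
    g2 = gm.column(snp2_id)
    out = np.full(gm.n_patients, GROUP_UNASSIGNED, dtype=object)
    out[g1 == 2] = GROUP_SNP1_HOM
    rest = ~np.isnan(g1) & (g1 != 2)
    out[rest & (g2 == 2)] = GROUP_SNP2_HOM
    out[rest & ~np.isnan(g2) & (g2 != 2)] = GROUP_BASELINE
    return out


@dataclass
class CombinedGroupResult:
    """Cox contrasts vs baseline, KM curves and log-rank across the groups."""

    group_sizes: dict[str, int]
    contrasts: pd.DataFrame       # group, estimable, hr, ci_low, ci_high, p
    wald_stat: float
    wald_df: int
    wald_p: float
    km_curves: dict[str, SurvivalCurve]
    logrank: tuple[float, int, float]
    n_used: int


def combined_group_association(
    labels: np.ndarray,
    clinical: ClinicalTable,
    covariate_preset="SIM",
    endpoint: str = "pfs",
    strata_col: str | None = None,
) -> CombinedGroupResult:
    """Three-group survival comparison with baseline as reference.

    Fits a Cox model with indicators for the two non-baseline groups plus
    the preset covariates (optionally stratified by cohort for pooled
    analyses), and reports KM curves and the log-rank test across all
    groups present.  An empty non-baseline group flags that contrast as
    inestimable instead of failing.
    """
    labels = np.asarray(labels, dtype=object)
    assigned = labels != GROUP_UNASSIGNED
    if (labels == GROUP_BASELINE).sum() == 0:
        raise ValueError("baseline group is empty")
    time, event = clinical.endpoint(endpoint)
    covariates = _resolve_covariates(covariate_preset, clinical)
    design = build_design(clinical, covariates)

    sizes = {g: int((labels == g).sum()) for g in
             (GROUP_BASELINE, GROUP_SNP1_HOM, GROUP_SNP2_HOM, GROUP_UNASSIGNED)}
    groups = [GROUP_SNP1_HOM, GROUP_SNP2_HOM]
    present = [g for g in groups if sizes[g] > 0]
    ind = np.column_stack([(labels == g).astype(float) for g in present]) \
        if present else np.empty((labels.size, 0))
    X = np.column_stack([ind, design.to_numpy(float)]) if design.shape[1] else ind
    keep = assigned & ~np.isnan(time) & ~(np.isnan(X).any(axis=1) if X.size else False)
    n_used = int(keep.sum())

    hr = {g: float("nan") for g in groups}
    lo = dict(hr)
    hi = dict(hr)
    pv = dict(hr)
    wstat = wdf = wp = float("nan")
    if present:
        strata = clinical.data[strata_col].to_numpy()[keep] if strata_col else None
        fit = cox_fit(
            X[keep], time[keep], event[keep], strata=strata,
            names=present + list(design.columns),
        )
        ci = fit.conf_int()
        for i, g in enumerate(present):
            hr[g] = float(fit.hazard_ratios[i])
            lo[g], hi[g] = float(ci[i, 0]), float(ci[i, 1])
            pv[g] = float(fit.wald_p[i])
        wstat, wdf, wp = fit.joint_wald(np.arange(len(present)))
    contrasts = pd.DataFrame(
        {
            "group": groups,
            "estimable": [g in present for g in groups],
            "hr": [hr[g] for g in groups],
            "ci_low": [lo[g] for g in groups],
            "ci_high": [hi[g] for g in groups],
            "p": [pv[g] for g in groups],
        }
    )
    curves = {}
    for g in (GROUP_BASELINE, *present):
        m = (labels == g) & ~np.isnan(time)
        curves[g] = km(time[m], event[m])
    lr_mask = assigned & ~np.isnan(time)
    lr_labels = labels[lr_mask]
    if np.unique(lr_labels).size >= 2:
        lr = tuple(logrank(time[lr_mask], event[lr_mask], lr_labels))
    else:
        lr = (float("nan"), 0, float("nan"))
    return CombinedGroupResult(sizes, contrasts, float(wstat), int(wdf) if wdf == wdf else 0,
                               float(wp), curves, lr, n_used)
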