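"""SNP quality-control: Hardy-Weinberg exact test and cohort inclusion filters.

Discovery-cohort inclusion requires four criteria per SNP: (1) carrier
frequency (fraction of non-missing patients with at least one minor allele)
at least 10% and below 100%; (2) reference-population MAF at least 5%;
(3) call rate at least 90%; (4) a unique gene annotation.  Validation
cohorts only require an 80% call rate.  Hardy-Weinberg departures are
screened with the exact conditional test at p > 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GenotypeMatrix

__all__ = ["QCReport", "hwe_exact_p", "hwe_exact_p_all", "discovery_filter", "validation_filter"]

HWE_P_FLOOR = 1e-4  # SNPs require a HWE p-value strictly above this


@dataclass
class QCReport:
    """Per-SNP discovery QC flags plus the list of SNPs passing all of them."""

    table: pd.DataFrame  # snp_id, carrier_freq, carrier_freq_pass, ref_maf_pass,
    #                      call_rate, call_rate_pass, unique_gene_pass, hwe_p, kept
    kept: list[str]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one (two-sided by probability ordering).

    Returns 1.0 for monomorphic samples (no alternative configurations).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = 2 * n_hom_minor + n_het
    n_rare = min(n_minor, 2 * n - n_minor)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het | n, n_rare) up to a constant: multinomial x 2^het
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_exact_p_all(gm: GenotypeMatrix) -> np.ndarray:
    """Vector of HWE exact p-values, one per SNP (NaN where all calls missing)."""
    out = np.empty(gm.n_snps)
    for j, snp_id in enumerate(gm.snp_ids):
        a, b, c = gm.genotype_counts(snp_id)
        out[j] = np.nan if a + b + c == 0 else hwe_exact_p(a, b, c)
    return out


def discovery_filter(
    gm: GenotypeMatrix,
    ref_maf_table: dict[str, float],
    gene_map: dict[str, str],
    min_carrier_freq: float = 0.10,
    min_ref_maf: float = 0.05,
    min_call_rate: float = 0.90,
) -> QCReport:
    """Apply the four discovery inclusion criteria to every SNP.

    Carrier frequency is computed over non-missing patients.  A SNP absent
    from ``ref_maf_table`` fails the reference-MAF criterion; one mapped to
    zero genes or to an ambiguous annotation (empty or comma-separated
    entry in ``gene_map``) fails the unique-gene criterion.  "At least"
    thresholds are inclusive; the 100% carrier bound is exclusive.
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    nonmiss = ~np.isnan(gm.codes)
    n_nonmiss = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore"):
        carrier = np.where(
            n_nonmiss > 0,
            np.nansum(gm.codes >= 1, axis=0) / np.maximum(n_nonmiss, 1),
            0.0,
        )
    call_rate = gm.call_rate()
    rows = []
    for j, snp_id in enumerate(gm.snp_ids):
        ref_maf = ref_maf_table.get(snp_id)
        gene = gene_map.get(snp_id, "")
        unique_gene = bool(gene) and ("," not in gene)
        cf_pass = (carrier[j] >= min_carrier_freq) and (carrier[j] < 1.0)
        maf_pass = ref_maf is not None and ref_maf >= min_ref_maf
        cr_pass = call_rate[j] >= min_call_rate
        a, b, c = gm.genotype_counts(snp_id)
        hwe_p = np.nan if a + b + c == 0 else hwe_exact_p(a, b, c)
        rows.append(
            dict(
                snp_id=snp_id,
                carrier_freq=carrier[j],
                carrier_freq_pass=cf_pass,
                ref_maf_pass=maf_pass,
                call_rate=call_rate[j],
                call_rate_pass=cr_pass,
                unique_gene_pass=unique_gene,
                hwe_p=hwe_p,
                kept=cf_pass and maf_pass and cr_pass and unique_gene,
            )
        )
    table = pd.DataFrame(rows)
    return QCReport(table, kept=list(table.loc[table["kept"], "snp_id"]))


def validation_filter(gm: GenotypeMatrix, min_call_rate: float = 0.80) -> list[str]:
    """SNP ids callable in at least ``min_call_rate`` of patients (inclusive)."""
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    keep = gm.call_rate() >= min_call_rate
    return [s for s, k in zip(gm.snp_ids, keep) if k]
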