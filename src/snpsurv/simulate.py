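"""Synthetic cohort generator: HWE genotypes, LD blocks, covariates, survival.

The generator emulates the statistical structure the analysis assumes for a
bevacizumab + chemotherapy pharmacogenomics cohort: genotypes in
Hardy-Weinberg equilibrium with a configurable MAF spectrum, optional LD
blocks drawn from explicit haplotype pools, clinical covariates (sex, age,
KRAS status), and right-censored progression-free / overall survival from a
proportional-hazards model with a handful of planted SNP effects.  Defaults
target a metastatic colorectal cancer first-line setting: median PFS around
300 days, median OS around 750 days, administrative censoring at three
(PFS) and five (OS) years.

The printed patient-characteristic contingency tables of the three study
cohorts (APD, MAVERICC, TRIBE) are embedded as named fixtures for the
contingency-test machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, GenotypeMatrix, SNP_COLUMNS

__all__ = [
    "SNPSpec",
    "LDBlockSpec",
    "EffectSpec",
    "SurvivalGenConfig",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_survival",
    "simulate_cohort",
    "table1_fixtures",
]


@dataclass(frozen=True)
class SNPSpec:
    """One simulated SNP: id, minor-allele frequency in [0, 0.5], gene label."""

    snp_id: str
    maf: float
    gene: str = ""
    ld_block: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class LDBlockSpec:
    """Haplotype pool for a set of co-inherited SNPs.

    ``haplotypes`` maps a tuple of 0/1 alleles (one per member, in order)
    to its population frequency; frequencies must sum to 1.
    """

    block_id: str
    members: tuple[str, ...]
    haplotypes: dict[tuple[int, ...], float]

    def __post_init__(self):
        tot = sum(self.haplotypes.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"block {self.block_id}: haplotype frequencies sum to {tot}")
        for hap in self.haplotypes:
            if len(hap) != len(self.members):
                raise ValueError(
                    f"block {self.block_id}: haplotype {hap} does not cover all members"
                )

    def marginal_maf(self, member: str) -> float:
        i = self.members.index(member)
        return sum(f for h, f in self.haplotypes.items() if h[i] == 1)


@dataclass(frozen=True)
class EffectSpec:
    """Planted SNP effect: genetic model and log hazard ratio."""

    snp_id: str
    genetic_model: str  # additive | dominant | recessive
    log_hazard_ratio: float

    def __post_init__(self):
        if self.genetic_model not in ("additive", "dominant", "recessive"):
            raise ValueError(f"unknown genetic model {self.genetic_model!r}")


@dataclass
class SurvivalGenConfig:
    """Exponential proportional-hazards generator settings (rates per day).

    Defaults give a median PFS of ~300 days and median OS of ~750 days at a
    zero linear predictor, with light independent exponential censoring and
    administrative censoring at 3 years (PFS) / 5 years (OS).
    """

    baseline_hazard: float = np.log(2) / 300.0
    censoring_rate: float = 1.0 / 1500.0
    admin_censor_time: float = 1095.0
    os_residual_hazard: float = np.log(2) / 450.0
    os_admin_censor_time: float = 1825.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0 or self.os_residual_hazard <= 0:
            raise ValueError("hazard and censoring rates must be positive")
        if self.admin_censor_time <= 0 or self.os_admin_censor_time <= 0:
            raise ValueError("administrative censoring times must be positive")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_patients: int,
    snp_specs: list[SNPSpec],
    ld_blocks: list[LDBlockSpec] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw an N x P genotype matrix in HWE with optional LD blocks.

    SNPs outside a block get two independent Bernoulli(maf) allele draws
    (hence HWE in expectation); block members get two haplotypes drawn
    from the block's pool.  Missing calls are masked independently at
    ``missing_rate``.  Fully reproducible from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    ids = [s.snp_id for s in snp_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_id in snp_specs")
    spec_by_id = {s.snp_id: s for s in snp_specs}
    ld_blocks = ld_blocks or []
    in_block: dict[str, LDBlockSpec] = {}
    for blk in ld_blocks:
        for m in blk.members:
            if m not in spec_by_id:
                raise ValueError(f"block {blk.block_id}: unknown member {m!r}")
            marg = blk.marginal_maf(m)
            if abs(marg - spec_by_id[m].maf) > 1e-6:
                raise ValueError(
                    f"block {blk.block_id}: member {m} marginal frequency "
                    f"{marg:.6f} inconsistent with spec maf {spec_by_id[m].maf:.6f}"
                )
            in_block[m] = blk

    rng = np.random.default_rng(seed)
    codes = np.empty((n_patients, len(ids)))
    col = {s: j for j, s in enumerate(ids)}
    free = [s for s in snp_specs if s.snp_id not in in_block]
    if free:
        mafs = np.array([s.maf for s in free])
        draws = rng.binomial(1, mafs, size=(n_patients, 2, len(free))).sum(axis=1)
        for j, s in enumerate(free):
            codes[:, col[s.snp_id]] = draws[:, j]
    for blk in ld_blocks:
        haps = np.array(list(blk.haplotypes.keys()), dtype=float)
        freqs = np.array(list(blk.haplotypes.values()))
        pick = rng.choice(len(haps), size=(n_patients, 2), p=freqs / freqs.sum())
        geno = haps[pick[:, 0]] + haps[pick[:, 1]]
        for i, m in enumerate(blk.members):
            codes[:, col[m]] = geno[:, i]
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = np.nan

    snps = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": np.arange(1, len(ids) + 1) * 1000,
            "major": "A",
            "minor": "C",
            "gene": [s.gene for s in snp_specs],
        }
    )[SNP_COLUMNS]
    return GenotypeMatrix([f"P{i:05d}" for i in range(n_patients)], snps, codes)


# ---------------------------------------------------------------------------
# Covariates and survival
# ---------------------------------------------------------------------------

def simulate_covariates(n_patients: int, seed: int = 0, cohort: str = "SIM") -> pd.DataFrame:
    """Clinical covariates: sex (M/F), age (years), KRAS status, cohort label."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n_patients)],
            "sex": rng.choice(["male", "female"], size=n_patients, p=[0.6, 0.4]),
            "age": np.clip(rng.normal(63.0, 10.0, n_patients).round(1), 25.0, 90.0),
            "kras": rng.choice(["wt", "mutant", "unknown"], size=n_patients, p=[0.47, 0.37, 0.16]),
            "cohort": cohort,
        }
    )


def _effect_column(gm: GenotypeMatrix, eff: EffectSpec) -> np.ndarray:
    g = np.nan_to_num(gm.column(eff.snp_id), nan=0.0)
    if eff.genetic_model == "additive":
        return g
    if eff.genetic_model == "dominant":
        return (g >= 1).astype(float)
    return (g == 2).astype(float)


def _covariate_lp(covariates: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(covariates))
    for name, loghr in effects.items():
        if name not in covariates.columns:
            raise ValueError(f"covariate_effects refers to unknown covariate {name!r}")
        s = covariates[name]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(float)
            x = x - x.mean()  # centred so baseline_hazard keeps its meaning
        else:
            ref = sorted(s.dropna().unique())[0]
            x = (s != ref).to_numpy(float)
        lp += loghr * x
    return lp


def simulate_survival(
    genotypes: GenotypeMatrix,
    clinical_covariates: pd.DataFrame,
    effects: list[EffectSpec],
    config: SurvivalGenConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (pfs_time, pfs_event, os_time, os_event) under proportional hazards.

    The latent relapse time is exponential with rate
    ``baseline_hazard * exp(lp)``; censoring is the minimum of an
    independent exponential draw and administrative cut-off.  The latent
    death time is the relapse time plus an exponential residual sharing the
    same linear predictor (so OS >= PFS by construction), censored on its
    own, longer scale.
    """
    for eff in effects:
        if eff.snp_id not in genotypes.snp_ids:
            raise ValueError(f"effect refers to unknown snp_id {eff.snp_id!r}")
    n = genotypes.n_patients
    if len(clinical_covariates) != n:
        raise ValueError("covariate rows do not match the genotype matrix")
    lp = _covariate_lp(clinical_covariates, config.covariate_effects)
    for eff in effects:
        lp = lp + eff.log_hazard_ratio * _effect_column(genotypes, eff)

    rng = np.random.default_rng(config.seed)
    risk = np.exp(lp)
    t_event = rng.exponential(1.0 / (config.baseline_hazard * risk))
    t_cens = np.minimum(
        rng.exponential(1.0 / config.censoring_rate, n), config.admin_censor_time
    )
    pfs_time = np.minimum(t_event, t_cens)
    pfs_event = (t_event <= t_cens).astype(int)

    t_death = t_event + rng.exponential(1.0 / (config.os_residual_hazard * risk))
    t_cens_os = np.minimum(
        rng.exponential(1.0 / config.censoring_rate, n), config.os_admin_censor_time
    )
    os_time = np.minimum(t_death, t_cens_os)
    os_event = (t_death <= t_cens_os).astype(int)
    return pfs_time, pfs_event, os_time, os_event


def simulate_cohort(
    n_patients: int,
    snp_specs: list[SNPSpec],
    effects: list[EffectSpec] | None = None,
    ld_blocks: list[LDBlockSpec] | None = None,
    config: SurvivalGenConfig | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    cohort: str = "SIM",
) -> tuple[GenotypeMatrix, ClinicalTable]:
    """One-call cohort: genotypes + covariates + PFS/OS endpoints.

    Component seeds are derived from ``seed`` by fixed offsets (genotypes:
    seed, covariates: seed + 1, survival: seed + 2) so any part can be
    regenerated independently.
    """
    gm = simulate_genotypes(n_patients, snp_specs, ld_blocks, missing_rate, seed)
    cov = simulate_covariates(n_patients, seed + 1, cohort)
    cfg = config or SurvivalGenConfig()
    cfg.seed = seed + 2
    pfs_t, pfs_e, os_t, os_e = simulate_survival(gm, cov, effects or [], cfg)
    data = cov.copy()
    data["pfs_time"] = pfs_t
    data["pfs_event"] = pfs_e
    data["os_time"] = os_t
    data["os_event"] = os_e
    return gm, ClinicalTable(data)


# ---------------------------------------------------------------------------
# Printed cohort-characteristics tables (contingency fixtures)
# ---------------------------------------------------------------------------

def table1_fixtures() -> dict[str, pd.DataFrame]:
    """Published patient-characteristic contingency tables, by name.

    Row/column labelled counts for the APD, MAVERICC and TRIBE cohorts:
    chemotherapy backbone, KRAS status (incl. unknown), primary tumour
    side (excl. unknown), BRAF status (excl. unknown; APD vs TRIBE),
    adjuvant chemotherapy, sex, and dichotomised age.
    """
    def t(rows, cols, data):
        return pd.DataFrame(data, index=rows, columns=cols)

    apd_mav_tribe = ["APD", "MAVERICC", "TRIBE"]
    return {
        "backbone": t(
            ["FP-based", "Non-FP"], apd_mav_tribe, [[177, 163, 215], [3, 0, 0]]
        ),
        "kras_with_unknown": t(
            ["wt", "mutant", "unknown"], apd_mav_tribe,
            [[87, 87, 88], [60, 56, 90], [33, 20, 37]],
        ),
        "primary_site": t(
            ["right", "left"], ["MAVERICC", "TRIBE"], [[67, 53], [96, 147]]
        ),
        "braf": t(["wt", "mutant"], ["APD", "TRIBE"], [[153, 168], [18, 10]]),
        "adjuvant": t(["no", "yes"], ["MAVERICC", "TRIBE"], [[143, 188], [20, 27]]),
        "sex": t(
            ["male", "female"], apd_mav_tribe, [[108, 103, 132], [72, 60, 83]]
        ),
        "age": t(["<=65", ">65"], apd_mav_tribe, [[77, 101, 156], [99, 62, 59]]),
    }
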