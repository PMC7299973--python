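"""Config-driven orchestration: simulate -> qc -> discover -> validate -> evaluate.

A YAML config (validated with pydantic before any computation) names either
input files (VCF, clinical TSV, reference MAF table, gene map) or a
simulation spec, plus the stability-selection and testing parameters.
Every stage writes TSV outputs and a JSON manifest (seeds, config hash,
package version, thresholds) sufficient to reproduce its outputs
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .association import (
    adjusted_scan,
    genotype_distribution_fisher,
    combined_group_association,
    permutation_corrected_logrank,
    two_snp_groups,
)
from .evaluate import ModelSpec, pec_compare
from .io import (
    ClinicalTable,
    read_clinical_tsv,
    read_two_column_tsv,
    read_vcf,
    write_clinical_tsv,
    write_vcf,
)
from .qc import discovery_filter, hwe_exact_p_all, validation_filter
from .simulate import EffectSpec, SNPSpec, SurvivalGenConfig, simulate_cohort
from .stability import candidate_set, post_hwe_filter, run_stability

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for schema-invalid or inconsistent pipeline configuration."""


class SimEffect(BaseModel):
    snp_id: str
    genetic_model: Literal["additive", "dominant", "recessive"] = "dominant"
    log_hazard_ratio: float


class SimulationSpec(BaseModel):
    n_patients: int = Field(180, ge=2)
    n_snps: int = Field(200, ge=1)
    maf_min: float = Field(0.05, ge=0.0, le=0.5)
    maf_max: float = Field(0.5, ge=0.0, le=0.5)
    missing_rate: float = Field(0.0, ge=0.0, lt=1.0)
    effects: list[SimEffect] = []
    cohort: str = "SIM"

    @field_validator("maf_max")
    @classmethod
    def _ordered(cls, v, info):
        if "maf_min" in info.data and v < info.data["maf_min"]:
            raise ValueError("maf_max < maf_min")
        return v


class StabilityParams(BaseModel):
    alphas: list[float] = [1.0, 0.5]
    n_repeats: int = Field(1000, ge=0)
    subsample: float = Field(0.9, gt=0.0, le=1.0)
    k: int = Field(3, ge=2)
    th_lasso: float = 0.25
    th_en: float = 0.70
    n_lambda: int = 100


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "snpsurv_out"
    endpoint: Literal["pfs", "os"] = "pfs"
    covariate_preset: Union[str, list[str]] = "SIM"
    simulation: Optional[SimulationSpec] = None
    vcf: Optional[str] = None
    clinical_tsv: Optional[str] = None
    ref_maf_tsv: Optional[str] = None
    gene_map_tsv: Optional[str] = None
    validation_vcf: Optional[str] = None
    validation_clinical_tsv: Optional[str] = None
    validation_covariate_preset: Union[str, list[str]] = "SIM"
    stability: StabilityParams = StabilityParams()
    permutation_B: int = Field(10000, ge=1)
    combine_pair: Optional[tuple[str, str]] = None
    pec_snp_counts: list[int] = [2, 5]
    pec_bootstrap_B: int = 50


def load_config(path) -> PipelineConfig:
    """Parse + schema-validate a YAML config; raises ConfigError, writes nothing."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError or YAML error
        raise ConfigError(str(exc)) from exc


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out: Path, config: PipelineConfig, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "snpsurv_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.model_dump(),
        **extra,
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _load_cohort(config: PipelineConfig, validation: bool = False):
    vcf = config.validation_vcf if validation else config.vcf
    tsv = config.validation_clinical_tsv if validation else config.clinical_tsv
    out = Path(config.out_dir)
    if vcf is None and config.simulation is not None:
        vcf = out / "genotypes.vcf"
        tsv = out / "clinical.tsv"
    if vcf is None or tsv is None:
        raise ConfigError("no input files and no simulation spec in config")
    gm = read_vcf(vcf)
    ct = read_clinical_tsv(tsv)
    if ct.patient_ids != gm.patient_ids:
        raise ConfigError("clinical table and VCF patient ids do not match")
    return gm, ct


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: PipelineConfig) -> dict:
    """Write a synthetic cohort: VCF, clinical TSV, ground-truth effects JSON.

    Also emits the reference-MAF table and gene map the QC stage consumes
    (true simulation MAFs; one gene per SNP).
    """
    if config.simulation is None:
        raise ConfigError("cmd_simulate requires a 'simulation' section")
    sim = config.simulation
    out = Path(config.out_dir)
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(sim.maf_min, sim.maf_max, sim.n_snps)
    specs = [
        SNPSpec(f"snp{j:05d}", float(mafs[j]), gene=f"gene{j:05d}")
        for j in range(sim.n_snps)
    ]
    known = {s.snp_id for s in specs}
    effects = []
    for e in sim.effects:
        if e.snp_id not in known:
            raise ConfigError(f"effect refers to unknown SNP {e.snp_id!r}")
        effects.append(EffectSpec(e.snp_id, e.genetic_model, e.log_hazard_ratio))
    out.mkdir(parents=True, exist_ok=True)
    gm, ct = simulate_cohort(
        sim.n_patients, specs, effects,
        config=SurvivalGenConfig(), missing_rate=sim.missing_rate,
        seed=config.seed, cohort=sim.cohort,
    )
    write_vcf(gm, out / "genotypes.vcf")
    write_clinical_tsv(ct, out / "clinical.tsv")
    pd.DataFrame({"snp_id": [s.snp_id for s in specs],
                  "maf": [s.maf for s in specs]}).to_csv(
        out / "ref_maf.tsv", sep="\t", index=False)
    pd.DataFrame({"snp_id": [s.snp_id for s in specs],
                  "gene": [s.gene for s in specs]}).to_csv(
        out / "gene_map.tsv", sep="\t", index=False)
    with open(out / "effects.json", "w") as fh:
        json.dump([e.model_dump() for e in sim.effects], fh, indent=2)
    _write_manifest(out, config, "simulate", {"n_patients": sim.n_patients,
                                              "n_snps": sim.n_snps})
    return {"files": ["genotypes.vcf", "clinical.tsv", "effects.json",
                      "ref_maf.tsv", "gene_map.tsv"]}


def _qc(config: PipelineConfig):
    gm, ct = _load_cohort(config)
    out = Path(config.out_dir)
    ref_maf_path = config.ref_maf_tsv or out / "ref_maf.tsv"
    gene_map_path = config.gene_map_tsv or out / "gene_map.tsv"
    ref_maf = read_two_column_tsv(ref_maf_path, "maf", numeric=True)
    gene_map = read_two_column_tsv(gene_map_path, "gene")
    report = discovery_filter(gm, ref_maf, gene_map)
    return gm, ct, report


def cmd_qc(config: PipelineConfig) -> dict:
    gm, ct, report = _qc(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "qc_report.tsv")
    log.info("qc: %d/%d SNPs kept", len(report.kept), gm.n_snps)
    _write_manifest(out, config, "qc", {"n_kept": len(report.kept)})
    return {"n_kept": len(report.kept), "n_snps": gm.n_snps}


def cmd_discover(config: PipelineConfig) -> dict:
    """QC -> stability selection (each alpha) -> thresholds -> HWE -> Cox scan."""
    gm, ct, report = _qc(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "qc_report.tsv")
    gm_q = gm.subset(snp_ids=report.kept)
    st = config.stability
    profiles = {}
    for alpha in st.alphas:
        prof = run_stability(
            gm_q, ct, alpha, n_repeats=st.n_repeats, subsample=st.subsample,
            k=st.k, master_seed=config.seed, endpoint=config.endpoint,
            n_lambda=st.n_lambda,
        )
        profiles[alpha] = prof
        prof.to_tsv(out / f"profile_alpha{alpha:g}.tsv")
        log.info("stability alpha=%g: mean nonzero size %.1f",
                 alpha, prof.mean_nonzero_size())
    p_lasso = profiles.get(1.0) or profiles[max(profiles)]
    p_en = profiles.get(0.5) or profiles[min(profiles)]
    candidates = candidate_set(p_lasso, p_en, st.th_lasso, st.th_en)
    kept, dropped = post_hwe_filter(candidates, gm_q)
    pd.DataFrame({"snp_id": kept}).to_csv(out / "candidates.tsv", sep="\t", index=False)
    if kept:
        scan = adjusted_scan(kept, gm_q, ct, config.covariate_preset,
                             config.endpoint)
        scan.to_csv(out / "associations.tsv", sep="\t", index=False)
        corrected = [
            permutation_corrected_logrank(
                gm_q, s, ct, config.endpoint, B=config.permutation_B,
                seed=config.seed,
            )
            for s in kept
        ]
        pd.DataFrame(
            {"snp_id": kept,
             "logrank_p": [c[0] for c in corrected],
             "corrected_p": [c[1] for c in corrected]}
        ).to_csv(out / "logrank_corrected.tsv", sep="\t", index=False)
    _write_manifest(out, config, "discover", {
        "n_candidates": len(kept), "hwe_dropped": dropped,
        "thresholds": {"lasso": st.th_lasso, "en": st.th_en},
    })
    return {"candidates": kept, "hwe_dropped": dropped}


def cmd_validate(config: PipelineConfig, candidates: list[str]) -> dict:
    """Validation-cohort checks for externally supplied candidate SNPs."""
    gm_d, _ct_d = _load_cohort(config)
    gm_v, ct_v = _load_cohort(config, validation=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    accessible = [s for s in candidates if s in gm_v.snp_ids]
    not_accessible = [s for s in candidates if s not in gm_v.snp_ids]
    covered = set(validation_filter(gm_v.subset(snp_ids=accessible))) if accessible else set()
    rows = []
    for s in accessible:
        hwe = hwe_exact_p_all(gm_v.subset(snp_ids=[s]))[0]
        fisher = (
            genotype_distribution_fisher(gm_d, gm_v, s)
            if s in gm_d.snp_ids else float("nan")
        )
        rows.append(dict(snp_id=s, covered=s in covered, hwe_p=hwe,
                         genotype_fisher_p=fisher))
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "validation_summary.tsv", sep="\t", index=False)
    usable = [s for s in accessible if s in covered]
    if usable:
        scan = adjusted_scan(usable, gm_v, ct_v,
                             config.validation_covariate_preset, config.endpoint)
        scan.to_csv(out / "validation_associations.tsv", sep="\t", index=False)
    _write_manifest(out, config, "validate", {
        "n_accessible": len(accessible), "not_accessible": not_accessible,
    })
    return {"accessible": accessible, "not_accessible": not_accessible,
            "summary": summary}


def cmd_combine(config: PipelineConfig) -> dict:
    """Two-SNP combined-genotype survival analysis on the configured pair."""
    if config.combine_pair is None:
        raise ConfigError("cmd_combine requires 'combine_pair' in config")
    s1, s2 = config.combine_pair
    gm, ct = _load_cohort(config)
    labels = two_snp_groups(gm, s1, s2)
    res = combined_group_association(labels, ct, config.covariate_preset,
                                     config.endpoint)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.contrasts.to_csv(out / "combined_groups.tsv", sep="\t", index=False)
    _write_manifest(out, config, "combine", {
        "pair": [s1, s2], "group_sizes": res.group_sizes,
        "logrank_p": res.logrank[2],
    })
    return {"result": res}


def cmd_evaluate(config: PipelineConfig, snp_lists: dict[str, list[str]] | None = None) -> dict:
    """Prediction-error-curve comparison: null vs clinical vs clinical+SNP models."""
    gm, ct = _load_cohort(config)
    from .association import _resolve_covariates
    covariates = tuple(_resolve_covariates(config.covariate_preset, ct))
    specs = [ModelSpec("null", null=True), ModelSpec("clinical", covariates=covariates)]
    if snp_lists is None:
        cand_path = Path(config.out_dir) / "candidates.tsv"
        snp_lists = {}
        if cand_path.exists():
            cands = list(pd.read_csv(cand_path, sep="\t")["snp_id"])
            for m in config.pec_snp_counts:
                if len(cands) >= m:
                    snp_lists[f"clinical+{m}snps"] = cands[:m]
    for label, snps in snp_lists.items():
        specs.append(ModelSpec(label, covariates=covariates, snp_ids=tuple(snps)))
    curve = pec_compare(specs, gm, ct, config.endpoint,
                        bootstrap_B=config.pec_bootstrap_B, seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_tsv(out / "pec.tsv")
    _write_manifest(out, config, "evaluate", {"models": [s.label for s in specs]})
    return {"curve": curve}


def cmd_report(config: PipelineConfig) -> dict:
    """Collect the stage manifests of a finished run."""
    out = Path(config.out_dir)
    manifests = {}
    for p in sorted(out.glob("manifest_*.json")):
        with open(p) as fh:
            manifests[p.stem.removeprefix("manifest_")] = json.load(fh)
    if not manifests:
        raise ConfigError(f"no manifests found under {out}")
    return {"manifests": manifests}
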