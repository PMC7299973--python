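import numpy as np
import pandas as pd
import pytest

from snpsurv.io import SNP_COLUMNS, ClinicalTable, GenotypeMatrix
from snpsurv.simulate import EffectSpec, SNPSpec, simulate_cohort


def make_gm(codes, snp_ids=None, genes=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw code array (NaN = missing)."""
    codes = np.asarray(codes, dtype=float)
    n, p = codes.shape
    snp_ids = snp_ids or [f"rs{j}" for j in range(p)]
    genes = genes or [f"G{j}" for j in range(p)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, p + 1) * 100,
            "major": "A",
            "minor": "C",
            "gene": genes,
        }
    )[SNP_COLUMNS]
    return GenotypeMatrix([f"P{i}" for i in range(n)], snps, codes)


def make_clinical(time, event, gm=None, **extra) -> ClinicalTable:
    time = np.asarray(time, dtype=float)
    n = time.size
    ids = gm.patient_ids if gm is not None else [f"P{i}" for i in range(n)]
    data = pd.DataFrame(
        {
            "patient_id": ids,
            "pfs_time": time,
            "pfs_event": np.asarray(event, dtype=int),
            "os_time": time * 2,
            "os_event": np.asarray(event, dtype=int),
            "cohort": "SIM",
            **extra,
        }
    )
    return ClinicalTable(data)


@pytest.fixture(scope="session")
def planted_cohort():
    """200 patients, 10 SNPs, one planted dominant log-HR = log 2 at rs0."""
    specs = [SNPSpec(f"rs{j}", 0.3, gene=f"G{j}") for j in range(10)]
    gm, ct = simulate_cohort(
        200, specs, [EffectSpec("rs0", "dominant", np.log(2))], seed=42
    )
    return gm, ct


@pytest.fixture(scope="session")
def small_survival():
    """A modest single-sample survival dataset with censoring and ties."""
    rng = np.random.default_rng(7)
    n = 120
    x = rng.binomial(2, 0.3, n).astype(float)
    t = np.round(rng.exponential(100 * np.exp(-0.4 * x)), 0) + 1
    c = rng.exponential(150, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return x, time, event
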