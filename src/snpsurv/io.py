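"""Genotype and clinical data containers, VCF/TSV round-trips, genetic-model encodings.

Genotypes are held as minor-allele counts: 0 (major homozygote), 1
(heterozygote), 2 (minor homozygote), ``NaN`` missing.  The minor allele is
defined per SNP as the less frequent allele in the data at hand (ties broken
toward ALT), so a matrix read from VCF is always "oriented": every coded
allele frequency is <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ClinicalTable",
    "read_vcf",
    "write_vcf",
    "encode",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_two_column_tsv",
]

GENETIC_MODELS = ("additive", "dominant", "recessive", "codominant")

#: metadata columns every GenotypeMatrix.snps frame carries
SNP_COLUMNS = ["snp_id", "chrom", "pos", "major", "minor", "gene"]


@dataclass
class GenotypeMatrix:
    """N patients x P SNPs coded as minor-allele counts.

    Parameters
    ----------
    patient_ids : list of str
        Ordered, unique patient identifiers (rows of ``codes``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, major, minor,
        gene`` (columns of ``codes``).
    codes : numpy.ndarray, shape (N, P), dtype float
        Minor-allele counts in {0, 1, 2}; ``NaN`` marks a missing call.
    """

    patient_ids: list[str]
    snps: pd.DataFrame
    codes: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.patient_ids), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.codes[~ok])
            raise ValueError(f"genotype codes outside {{0,1,2,NaN}}: {bad}")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup!r}")
        self.snps = self.snps.reset_index(drop=True)
        self._index = {s: j for j, s in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        """Genotype codes for one SNP (copy), NaN for missing."""
        try:
            j = self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id: {snp_id!r}") from None
        return self.codes[:, j].copy()

    def maf(self) -> np.ndarray:
        """Per-SNP coded (minor) allele frequency among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=0)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts among non-missing calls."""
        g = self.column(snp_id)
        g = g[~np.isnan(g)]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    def subset(self, patient_idx=None, snp_ids=None) -> "GenotypeMatrix":
        """Row/column subset; order of arguments is preserved in the result."""
        pidx = np.arange(self.n_patients) if patient_idx is None else np.asarray(patient_idx)
        if snp_ids is None:
            cols = np.arange(self.n_snps)
        else:
            cols = np.array([self._index[s] for s in snp_ids])
        return GenotypeMatrix(
            [self.patient_ids[i] for i in pidx],
            self.snps.iloc[cols].reset_index(drop=True),
            self.codes[np.ix_(pidx, cols)],
        )

    def oriented(self) -> "GenotypeMatrix":
        """Re-orient so every coded allele frequency is <= 0.5.

        SNPs whose coded frequency exceeds 0.5 have codes flipped (2 - code)
        and major/minor labels swapped.  Idempotent: orienting an oriented
        matrix is the identity.
        """
        freq = self.maf()
        flip = freq > 0.5
        if not flip.any():
            return self
        codes = self.codes.copy()
        codes[:, flip] = 2.0 - codes[:, flip]
        snps = self.snps.copy()
        maj = snps.loc[flip, "major"].copy()
        snps.loc[flip, "major"] = snps.loc[flip, "minor"].values
        snps.loc[flip, "minor"] = maj.values
        return GenotypeMatrix(list(self.patient_ids), snps, codes)


@dataclass
class ClinicalTable:
    """Per-patient covariates and survival endpoints.

    ``data`` carries one row per patient, indexed 0..N-1, with at least
    ``patient_id``, ``pfs_time``, ``pfs_event``, ``os_time``, ``os_event``
    and ``cohort``; any additional columns are treated as covariates
    (categorical if non-numeric).
    """

    data: pd.DataFrame

    REQUIRED = ("patient_id", "pfs_time", "pfs_event", "os_time", "os_event", "cohort")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        for tcol in ("pfs_time", "os_time"):
            if (self.data[tcol] < 0).any():
                raise ValueError(f"{tcol} contains negative times")
        for ecol in ("pfs_event", "os_event"):
            if not self.data[ecol].isin([0, 1]).all():
                raise ValueError(f"{ecol} must be binary 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for endpoint 'pfs' or 'os'."""
        which = which.lower()
        if which not in ("pfs", "os"):
            raise ValueError(f"endpoint must be 'pfs' or 'os', got {which!r}")
        return (
            self.data[f"{which}_time"].to_numpy(float),
            self.data[f"{which}_event"].to_numpy(int),
        )

    def aligned_with(self, gm: GenotypeMatrix) -> bool:
        return self.patient_ids == gm.patient_ids


# ---------------------------------------------------------------------------
# VCF I/O (biallelic GT-only subset, via cyvcf2 for reading)
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene">\n'
)


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic, GT-only VCF into an oriented :class:`GenotypeMatrix`.

    Phasing separators ("/" or "|") are ignored; ``./.`` becomes missing.
    The minor allele is the less frequent of REF/ALT in the file (ALT on
    ties); codes count minor alleles.  Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    patient_ids = list(vcf.samples)
    rows, alt_counts = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record not supported: {var.CHROM}:{var.POS} "
                f"ALT={var.ALT}"
            )
        gene = var.INFO.get("GENE") or ""
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0], gene))
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        cnt = np.where(gt == 3, 2.0, gt)
        cnt[gt == 2] = np.nan
        alt_counts.append(cnt)
    vcf.close()
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "gene"])
    codes = (
        np.column_stack(alt_counts) if alt_counts
        else np.empty((len(patient_ids), 0))
    )
    # ALT-count coding first (major=REF, minor=ALT), then orient.
    snps = snps.rename(columns={"ref": "major", "alt": "minor"})[SNP_COLUMNS]
    return GenotypeMatrix(patient_ids, snps, codes).oriented()


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF v4.2 text file.

    REF is the major allele and ALT the minor, so ``read_vcf(write_vcf(gm))``
    reproduces codes and metadata exactly for an oriented matrix.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(gm.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.patient_ids) + "\n")
        gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in gm.snps.iterrows():
            info = f"GENE={snp.gene}" if snp.gene else "."
            cells = [
                gt_strings.get(c, "./.") for c in gm.codes[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.major}\t{snp.minor}"
                f"\t.\t.\t{info}\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Genetic-model encodings
# ---------------------------------------------------------------------------

def encode(gm: GenotypeMatrix, snp_id: str, model: str, flip: bool = False):
    """Encode one SNP under a genetic model.

    Parameters
    ----------
    model : {"additive", "dominant", "recessive", "codominant"}
        additive: minor-allele count as-is.  dominant: carrier of >= 1 minor
        allele.  recessive: minor homozygote.  codominant: two indicator
        columns (het, hom_minor) with the major homozygote as reference.
    flip : bool
        Encode with respect to the *major* allele instead (code -> 2 - code
        first).  This expresses groupings such as "any major-allele carrier"
        without re-orienting the matrix.

    Returns
    -------
    numpy.ndarray
        Shape (N,) for additive/dominant/recessive, (N, 2) for codominant.
        Missing genotypes propagate as NaN.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS}")
    g = gm.column(snp_id)
    if flip:
        g = 2.0 - g
    miss = np.isnan(g)
    if model == "additive":
        return g
    if model == "dominant":
        out = (g >= 1).astype(float)
    elif model == "recessive":
        out = (g == 2).astype(float)
    else:  # codominant
        out = np.column_stack([(g == 1), (g == 2)]).astype(float)
        out[miss] = np.nan
        return out
    out[miss] = np.nan
    return out


# ---------------------------------------------------------------------------
# Tabular helpers
# ---------------------------------------------------------------------------

def read_clinical_tsv(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t", dtype={"patient_id": str}))


def write_clinical_tsv(ct: ClinicalTable, path) -> None:
    ct.data.to_csv(path, sep="\t", index=False)


def read_two_column_tsv(path, value_name: str, numeric: bool = False) -> dict:
    """Read a (snp_id, value) TSV such as a reference-MAF table or gene map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (snp_id, {value_name})")
    key, val = df.columns[:2]
    values = df[val].astype(float) if numeric else df[val].astype(str)
    return dict(zip(df[key].astype(str), values))
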