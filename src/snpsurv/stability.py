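"""Repeated-subsample stability selection over penalized Cox models.

Each repeat draws a random 90% patient subset without replacement, runs a
K-fold cross-validated elastic-net (or LASSO) Cox path on the additive SNP
dosages, and records the SNPs in the nonzero set at the deviance-minimising
lambda.  Selection counts over many repeats give per-SNP selection
frequencies; candidates are SNPs exceeding an algorithm-specific frequency
threshold (strict ">25%" of repeats for LASSO, ">=70%" for elastic net
alpha = 0.5), optionally post-filtered for Hardy-Weinberg departures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import cv_coxnet
from .io import ClinicalTable, GenotypeMatrix
from .qc import hwe_exact_p

__all__ = ["SelectionProfile", "dosage_matrix", "run_stability", "candidate_set", "post_hwe_filter"]

log = logging.getLogger(__name__)


def dosage_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Additive 0/1/2 codes with missing calls imputed to the SNP mean dosage."""
    X = gm.codes.copy()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


@dataclass
class SelectionProfile:
    """Per-SNP selection counts across stability-selection repeats."""

    alpha: float
    n_repeats: int
    subsample: float
    snp_ids: list[str]
    counts: np.ndarray          # completed-repeat selection count per SNP
    repeat_sizes: np.ndarray    # nonzero-set size per completed repeat
    n_skipped: int
    master_seed: int

    @property
    def n_completed(self) -> int:
        return self.n_repeats - self.n_skipped

    def frequency(self) -> np.ndarray:
        denom = max(self.n_completed, 1)
        return self.counts / denom

    def mean_nonzero_size(self) -> float:
        return float(self.repeat_sizes.mean()) if self.repeat_sizes.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "count": self.counts,
                "frequency": self.frequency(),
                "alpha": self.alpha,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_stability(
    gm: GenotypeMatrix,
    clinical: ClinicalTable,
    alpha: float,
    n_repeats: int = 1000,
    subsample: float = 0.9,
    k: int = 3,
    master_seed: int = 0,
    endpoint: str = "pfs",
    n_lambda: int = 50,
    dfmax: int = 30,
    max_skip_fraction: float = 0.05,
) -> SelectionProfile:
    """Selection counts over ``n_repeats`` random 90% subsamples.

    Repeat ``r`` uses seed ``master_seed + r`` for both the subsample draw
    (without replacement) and the fold split, so results are reproducible
    and independent of any parallel scheduling.  Repeats whose subsample
    cannot support ``k`` folds with events are skipped and logged; more
    than ``max_skip_fraction`` skips is an error.

    Paths are truncated once ``dfmax`` predictors are active: at desk-scale
    cohorts the cross-validated deviance minimum sits far below that, and
    the near-saturated tail of the path carries no selection information.
    """
    if not clinical.aligned_with(gm):
        raise ValueError("clinical table and genotype matrix patient ids differ")
    X = dosage_matrix(gm)
    time, event = clinical.endpoint(endpoint)
    n = gm.n_patients
    m = math.floor(subsample * n)
    counts = np.zeros(gm.n_snps, dtype=int)
    sizes = []
    n_skipped = 0
    for r in range(1, n_repeats + 1):
        seed = master_seed + r
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=m, replace=False)
        try:
            with warnings.catch_warnings():
                # near-saturated path tails flag an iteration cap; the
                # status is recorded on the path and harmless for selection
                warnings.filterwarnings("ignore", message="coxnet: .*iteration cap")
                cv = cv_coxnet(
                    X[idx], time[idx], event[idx], alpha,
                    k=k, fold_seed=seed, n_lambda=n_lambda, dfmax=dfmax,
                    min_ratio=0.05,
                )
        except ValueError as exc:
            n_skipped += 1
            log.warning("stability repeat %d skipped: %s", r, exc)
            continue
        counts[cv.nonzero_idx] += 1
        sizes.append(cv.nonzero_idx.size)
    if n_repeats and n_skipped / n_repeats > max_skip_fraction:
        raise RuntimeError(
            f"{n_skipped}/{n_repeats} stability repeats skipped "
            f"(> {max_skip_fraction:.0%}); cohort too sparse in events"
        )
    return SelectionProfile(
        float(alpha), n_repeats, subsample, gm.snp_ids, counts,
        np.asarray(sizes, dtype=int), n_skipped, master_seed,
    )


def candidate_set(
    profile_lasso: SelectionProfile,
    profile_en: SelectionProfile,
    th_lasso: float = 0.25,
    th_en: float = 0.70,
) -> list[str]:
    """Union of SNPs above the per-algorithm selection-frequency thresholds.

    The LASSO threshold is strict (selected in *more than* ``th_lasso`` of
    repeats); the elastic-net threshold is inclusive (``th_en`` *or more*).
    Profiles must share the SNP universe.
    """
    if profile_lasso.snp_ids != profile_en.snp_ids:
        raise ValueError("selection profiles cover different SNP universes")
    nl = profile_lasso.n_repeats
    ne = profile_en.n_repeats
    keep_l = profile_lasso.counts > th_lasso * nl
    # with zero repeats nothing was ever selected (0 >= 0 is vacuous)
    keep_e = (profile_en.counts >= th_en * ne) & (profile_en.counts > 0)
    return [s for s, k in zip(profile_lasso.snp_ids, keep_l | keep_e) if k]


def post_hwe_filter(
    candidates: list[str],
    gm: GenotypeMatrix,
    p_floor: float = 1e-4,
) -> tuple[list[str], list[str]]:
    """Drop candidates departing from HWE (exact test p <= ``p_floor``).

    Returns ``(kept, dropped)``; the rule requires p strictly above the
    floor, so a candidate exactly at the boundary is dropped.
    """
    unknown = [s for s in candidates if s not in gm.snp_ids]
    if unknown:
        raise ValueError(f"candidates absent from genotype matrix: {unknown}")
    kept, dropped = [], []
    for s in candidates:
        a, b, c = gm.genotype_counts(s)
        p = hwe_exact_p(a, b, c) if a + b + c else float("nan")
        (dropped if (not np.isnan(p) and p <= p_floor) else kept).append(s)
    return kept, dropped
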