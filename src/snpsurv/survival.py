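"""Survival machinery: Kaplan-Meier, log-rank, Cox proportional hazards.

All estimators are implemented on plain numpy arrays so that the
permutation-testing and stability-selection layers can call them tens of
thousands of times.  ``cox_fit`` maximises the partial likelihood by
Newton-Raphson with Efron (default) or Breslow tie handling and optional
stratification (separate baseline hazards per stratum, shared
coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .io import ClinicalTable, GenotypeMatrix, encode

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "AssociationRecord",
    "km",
    "logrank",
    "cox_fit",
    "genotype_association",
    "build_design",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate on the grid of distinct observed times."""

    times: np.ndarray        # distinct observed times, ascending
    survival: np.ndarray     # S(t) immediately after each time
    std_err: np.ndarray      # Greenwood standard error of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float            # smallest time with S <= 0.5, NaN if never reached
    median_ci: tuple[float, float]

    def survival_at(self, t, left: bool = False) -> np.ndarray:
        """Evaluate S(t) (right-continuous); ``left=True`` gives S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(self.times, t, side=side)
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood errors.

    The median is the smallest observed time where the estimate drops to
    0.5 or below (NaN if never reached); its CI comes from the crossing
    points of the pointwise 95% log-log confidence band.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0 or np.isnan(time).all():
        raise ValueError("no usable survival times")
    keep = ~np.isnan(time)
    time, event = time[keep], event[keep]
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    utimes, first = np.unique(time, return_index=True)
    n = time.size
    at_risk = n - first
    d = np.add.reduceat(event, first)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        # Greenwood: var(S) = S^2 * cumsum(d / (Y (Y - d)))
        gw = np.where(at_risk > d, d / (at_risk * (at_risk - d).astype(float)), np.inf)
        se = surv * np.sqrt(np.cumsum(gw))

    below = surv <= 0.5 + 1e-12
    median = float(utimes[below][0]) if below.any() else float("nan")
    # log-log 95% band crossing 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(-np.log(np.clip(surv, 1e-15, 1 - 1e-15)))
        sig = se / np.clip(surv * np.abs(np.log(np.clip(surv, 1e-15, None))), 1e-15, None)
        lo = np.exp(-np.exp(logs + 1.96 * sig))
        hi = np.exp(-np.exp(logs - 1.96 * sig))
    lo_cross = utimes[hi <= 0.5 + 1e-12]
    hi_cross = utimes[lo <= 0.5 + 1e-12]
    ci = (
        float(lo_cross[0]) if lo_cross.size else float("nan"),
        float(hi_cross[0]) if hi_cross.size else float("nan"),
    )
    return SurvivalCurve(utimes, surv, se, at_risk, d, median, ci)


def censoring_km(time, event) -> SurvivalCurve:
    """KM estimate of the censoring distribution G (censorings as events)."""
    return km(time, 1 - np.asarray(event, dtype=int))


# ---------------------------------------------------------------------------
# Log-rank (vectorised over permutation batches)
# ---------------------------------------------------------------------------

def _logrank_stats_batch(time, event, labels, n_groups: int) -> np.ndarray:
    """Log-rank chi-square statistics for each column of ``labels``.

    ``labels`` is (n, B) with integer group codes 0..n_groups-1; the
    survival data are shared across columns.  Returns (B,) statistics with
    df = n_groups - 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if labels.ndim == 1:
        labels = labels[:, None]
    order = np.argsort(time, kind="stable")
    time, event, labels = time[order], event[order], labels[order]
    n, B = labels.shape
    utimes, first = np.unique(time, return_index=True)
    k = utimes.size

    onehot = np.zeros((n, B, n_groups))
    np.put_along_axis(onehot, labels[:, :, None], 1.0, axis=2)

    # at-risk per group at each unique time: suffix sums evaluated at block starts
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]
    Yg = suffix[first]                      # (k, B, G)
    dg = np.add.reduceat(onehot * event[:, None, None], first, axis=0)  # (k, B, G)
    Y = Yg.sum(axis=2)                      # (k, B) total at risk
    d = dg.sum(axis=2)                      # (k, B) total deaths (same for all B)

    with np.errstate(divide="ignore", invalid="ignore"):
        Eg = d[:, :, None] * Yg / Y[:, :, None]
        cfac = np.where(Y > 1, d * (Y - d) / (Y - 1.0), 0.0) / np.maximum(Y, 1.0) ** 2
        # V_gh = sum_t cfac * (delta_gh * Yg * Y - Yg * Yh)
        V = -np.einsum("kb,kbg,kbh->bgh", cfac, Yg, Yg)
        diag = np.einsum("kb,kbg,kb->bg", cfac, Yg, Y)
        V[:, np.arange(n_groups), np.arange(n_groups)] += diag
    u = (dg - Eg).sum(axis=0)               # (B, G) observed - expected

    ur = u[:, : n_groups - 1]
    Vr = V[:, : n_groups - 1, : n_groups - 1]
    try:
        sol = np.linalg.solve(Vr, ur[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        sol = np.einsum("bij,bj->bi", np.linalg.pinv(Vr), ur)
    return np.einsum("bi,bi->b", ur, sol)


def logrank(time, event, group) -> tuple[float, int, float]:
    """Standard log-rank test across >= 2 groups.

    Returns ``(chi_square, df, p)`` with df = number of groups - 1.
    """
    group = np.asarray(group)
    levels, codes = np.unique(group, return_inverse=True)
    if levels.size < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    stat = float(_logrank_stats_batch(time, event, codes[:, None], levels.size)[0])
    df = levels.size - 1
    return stat, df, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Maximum partial-likelihood fit with Wald inference.

    ``hazard_ratios`` are exp(coefficients); confidence intervals are Wald
    intervals on the log scale, exponentiated.
    """

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    ties: str
    max_score: float
    _baseline: tuple | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2)
        return np.exp(
            np.column_stack([self.beta - z * self.se, self.beta + z * self.se])
        )

    @property
    def wald_p(self) -> np.ndarray:
        """Per-coefficient two-sided Wald p-values."""
        z = self.beta / self.se
        return 2 * norm.sf(np.abs(z))

    def joint_wald(self, idx) -> tuple[float, int, float]:
        """Joint Wald test that the coefficients at ``idx`` are all zero."""
        idx = np.atleast_1d(idx)
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = idx.size
        return stat, df, float(chi2.sf(stat, df))

    def baseline_cumhaz(self) -> tuple[np.ndarray, np.ndarray]:
        """Breslow baseline cumulative hazard (times, H0) of the first stratum."""
        if self._baseline is None:
            raise ValueError("baseline hazard not retained for this fit")
        return self._baseline

    def predict_survival(self, X_new, times) -> np.ndarray:
        """S(t | x) = exp(-H0(t) exp(x beta)) on the fit's baseline."""
        bt, bh = self.baseline_cumhaz()
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(bt, times, side="right") - 1
        H0 = np.where(idx >= 0, np.concatenate([[0.0], bh])[idx + 1], 0.0)
        risk = np.exp(np.asarray(X_new, dtype=float) @ self.beta)
        return np.exp(-np.outer(risk, H0))


def _cox_loglik_grad_hess(X, time, event, beta, ties, strata=None):
    """Log partial likelihood, score and observed information at ``beta``."""
    n, p = X.shape
    eta = X @ beta
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    if strata is None:
        strata = np.zeros(n, dtype=int)
    for s in np.unique(strata):
        m = strata == s
        ll_s, g_s, i_s = _cox_lgh_one(X[m], time[m], event[m], eta[m], ties)
        ll += ll_s
        grad += g_s
        info += i_s
    return ll, grad, info


def _cox_lgh_one(X, time, event, eta, ties):
    order = np.argsort(time, kind="stable")
    X, time, event, eta = X[order], time[order], event[order], eta[order]
    n, p = X.shape
    # overflow-safe risk scores
    c = eta.max() if n else 0.0
    r = np.exp(eta - c)
    rX = r[:, None] * X
    rXX = np.einsum("i,ij,ik->ijk", r, X, X)
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    S2 = np.cumsum(rXX[::-1], axis=0)[::-1]

    utimes, first = np.unique(time, return_index=True)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev = event.astype(bool)
    for i0 in first:
        t = time[i0]
        i1 = i0
        while i1 < n and time[i1] == t:
            i1 += 1
        tied = np.flatnonzero(ev[i0:i1]) + i0
        d = tied.size
        if d == 0:
            continue
        sr = S0[i0]
        zr = S1[i0]
        qr = S2[i0]
        ll += eta[tied].sum() - d * c
        grad += X[tied].sum(axis=0)
        if ties == "breslow":
            ll -= d * np.log(sr)
            grad -= d * zr / sr
            info += d * (qr / sr - np.outer(zr, zr) / sr**2)
        else:  # efron
            sd = r[tied].sum()
            zd = rX[tied].sum(axis=0)
            qd = rXX[tied].sum(axis=0)
            for l in range(d):
                f = l / d
                phi = sr - f * sd
                zz = zr - f * zd
                qq = qr - f * qd
                ll -= np.log(phi)
                grad -= zz / phi
                info += qq / phi - np.outer(zz, zz) / phi**2
    return ll, grad, info


def cox_fit(
    X,
    time,
    event,
    ties: str = "efron",
    strata=None,
    names: list[str] | None = None,
    max_iter: int = 60,
    score_tol: float = 1e-9,
    ll_tol: float = 1e-10,
    keep_baseline: bool = False,
) -> CoxFit:
    """Newton-Raphson maximisation of the Cox partial likelihood.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Complete design matrix; rows with any NaN (in X, time or event) are
        dropped with a warning stating the count.
    ties : {"efron", "breslow"}
    strata : array-like, optional
        Stratum labels; each stratum gets its own baseline hazard.

    Raises
    ------
    ValueError
        If no events remain, or a column is constant / collinear to
        tolerance.  Non-convergence (including monotone likelihood from
        perfect separation) is flagged on the result, never silent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(time).size > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(time) | np.isnan(event))
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"cox_fit: dropped {n_drop} rows with missing values")
        X, time, event = X[keep], time[keep], event[keep]
        if strata is not None:
            strata = np.asarray(strata)[keep]
    n, p = X.shape
    if event.sum() < 1:
        raise ValueError("cox_fit requires at least one event")
    sd = X.std(axis=0)
    if (sd < 1e-12).any():
        j = int(np.argmin(sd))
        raise ValueError(f"constant column in design matrix (index {j})")
    Xc = (X - X.mean(axis=0)) / sd
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise ValueError("collinear design matrix (singular to tolerance)")

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    max_score = np.inf
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik_grad_hess(X, time, event, beta, ties, strata)
        max_score = float(np.abs(grad).max())
        if max_score < score_tol:
            converged = True
            break
        if (
            np.isfinite(ll_prev)
            and abs(ll - ll_prev) <= ll_tol * (abs(ll) + 1e-12)
            and max_score < 1e-8
        ):
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the likelihood non-decreasing (relative
        # slack absorbs rounding noise in ll near the optimum)
        for _h in range(30):
            cand = beta + step
            ll_new = _cox_loglik_grad_hess(X, time, event, cand, ties, strata)[0]
            if ll_new >= ll - 1e-10 * (abs(ll) + 1.0):
                break
            step = step / 2
        beta = beta + step
        ll_prev = ll
        if np.abs(beta).max() > 100:
            break  # monotone likelihood / separation
    ll, grad, info = _cox_loglik_grad_hess(X, time, event, beta, ties, strata)
    max_score = float(np.abs(grad).max())
    if max_score < score_tol:
        converged = True
    if np.abs(beta).max() > 15:
        # a log hazard ratio beyond +-15 signals monotone likelihood
        # (perfect separation); the score vanishes numerically along the
        # ridge, so never report convergence there
        converged = False
    if not converged:
        warnings.warn(
            "cox_fit did not converge (possible monotone likelihood / "
            f"separation); max |score| = {max_score:.3g}"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    ll_null = _cox_loglik_grad_hess(X, time, event, np.zeros(p), ties, strata)[0]
    baseline = None
    if keep_baseline:
        baseline = _breslow_baseline(X, time, event, beta, strata)
    if names is None:
        names = [f"x{j}" for j in range(p)]
    return CoxFit(
        list(names), beta, cov, float(ll), float(ll_null),
        n, int(event.sum()), converged, ties, max_score, baseline,
    )


def _breslow_baseline(X, time, event, beta, strata=None):
    """Breslow cumulative baseline hazard of the first (or only) stratum."""
    if strata is not None:
        m = strata == np.unique(strata)[0]
        X, time, event = X[m], time[m], event[m]
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    r = np.exp(X[order] @ beta)
    S0 = np.cumsum(r[::-1])[::-1]
    utimes, first = np.unique(time, return_index=True)
    d = np.add.reduceat(event, first)
    h0 = d / S0[first]
    keep = d > 0
    return utimes[keep], np.cumsum(h0[keep])


# ---------------------------------------------------------------------------
# Covariate design + genotype association
# ---------------------------------------------------------------------------

def build_design(clinical: ClinicalTable, covariates: list[str]) -> pd.DataFrame:
    """Numeric design frame for the requested covariates.

    Non-numeric columns are dummy-coded with the first level as reference;
    numeric columns pass through.  Rows keep the clinical table's order.
    """
    cols = []
    for c in covariates:
        if c not in clinical.data.columns:
            raise KeyError(f"unknown covariate {c!r}")
        s = clinical.data[c]
        if s.notna().all() is False and s.isna().all():
            raise ValueError(f"covariate {c!r} is entirely missing")
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            dummies[s.isna().to_numpy()] = np.nan
            cols.append(dummies)
    if not cols:
        return pd.DataFrame(index=clinical.data.index)
    return pd.concat(cols, axis=1)


@dataclass
class AssociationRecord:
    """One SNP x genetic model association in Table-2 style."""

    snp_id: str
    gene: str
    model: str
    endpoint: str
    estimable: bool
    n_used: int
    group_sizes: dict[str, int]
    contrast_names: list[str]
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    coef_p: np.ndarray
    wald_stat: float
    wald_df: int
    wald_p: float
    message: str = ""

    def to_row(self) -> dict:
        row = dict(
            snp_id=self.snp_id, gene=self.gene, model=self.model,
            endpoint=self.endpoint, estimable=self.estimable, n=self.n_used,
            wald_stat=self.wald_stat, wald_df=self.wald_df, wald_p=self.wald_p,
            message=self.message,
        )
        for k, name in enumerate(self.contrast_names):
            row[f"hr_{name}"] = self.hazard_ratios[k]
            row[f"ci_low_{name}"] = self.ci_lower[k]
            row[f"ci_high_{name}"] = self.ci_upper[k]
            row[f"p_{name}"] = self.coef_p[k]
        return row


def _inestimable(snp_id, gene, model, endpoint, n, sizes, msg) -> AssociationRecord:
    e = np.array([])
    return AssociationRecord(
        snp_id, gene, model, endpoint, False, n, sizes, [], e, e, e, e,
        float("nan"), 0, float("nan"), msg,
    )


def genotype_association(
    gm: GenotypeMatrix,
    snp_id: str,
    model: str,
    clinical: ClinicalTable,
    covariates: list[str],
    endpoint: str = "pfs",
    flip: bool = False,
    ties: str = "efron",
    strata_col: str | None = None,
) -> AssociationRecord:
    """Covariate-adjusted Cox association for one SNP under one genetic model.

    Fits time-to-event ~ genotype encoding(s) + covariates on complete
    cases; patients missing the genotype are excluded for that SNP.  The
    across-genotype Wald test has 2 df for the codominant model (het and
    minor-homozygote contrasts vs major homozygotes) and 1 df otherwise.
    Degenerate groupings (an empty genotype group under the requested
    model) yield an inestimable record rather than an exception.
    """
    if model not in ("codominant", "dominant", "recessive", "additive"):
        raise ValueError(f"unsupported genetic model {model!r}")
    if not clinical.aligned_with(gm):
        raise ValueError("clinical table and genotype matrix patient ids differ")
    gene = str(gm.snps.set_index("snp_id").loc[snp_id, "gene"])
    time, event = clinical.endpoint(endpoint)
    enc = encode(gm, snp_id, model if model != "additive" else "additive", flip=flip)
    enc2 = enc if enc.ndim == 2 else enc[:, None]
    contrast_names = (
        ["het", "hom_minor"] if model == "codominant" else [model]
    )
    design = build_design(clinical, covariates)
    Xfull = np.column_stack([enc2, design.to_numpy(dtype=float)]) if design.shape[1] else enc2
    strata = clinical.data[strata_col].to_numpy() if strata_col else None
    keep = ~(np.isnan(Xfull).any(axis=1) | np.isnan(time) | np.isnan(event.astype(float)))
    Xc, tc, ec = Xfull[keep], time[keep], event[keep]
    sc = strata[keep] if strata is not None else None
    n_used = int(keep.sum())

    g = gm.column(snp_id)[keep]
    if flip:
        g = 2.0 - g
    sizes = {k: int((g == v).sum()) for k, v in (("hom_major", 0), ("het", 1), ("hom_minor", 2))}

    n_gcol = enc2.shape[1]
    for j in range(n_gcol):
        col = Xc[:, j]
        if col.size == 0 or col.std() < 1e-12:
            return _inestimable(
                snp_id, gene, model, endpoint, n_used, sizes,
                f"empty genotype group under {model} model",
            )
    try:
        fit = cox_fit(
            Xc, tc, ec, ties=ties, strata=sc,
            names=contrast_names + list(design.columns),
        )
    except ValueError as exc:
        return _inestimable(snp_id, gene, model, endpoint, n_used, sizes, str(exc))
    idx = np.arange(n_gcol)
    wstat, wdf, wp = fit.joint_wald(idx)
    ci = fit.conf_int()
    return AssociationRecord(
        snp_id, gene, model, endpoint, True, n_used, sizes, contrast_names,
        fit.hazard_ratios[idx], ci[idx, 0], ci[idx, 1], fit.wald_p[idx],
        wstat, wdf, wp,
        "" if fit.converged else "non-convergence flagged",
    )
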