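"""Model evaluation: IPCW Brier scores and bootstrapped prediction error curves.

The Brier score at horizon t is the mean squared distance between each
patient's survival status at t and the model's predicted survival
probability, reweighted for right-censoring by the inverse probability of
censoring (Kaplan-Meier estimate G of the censoring distribution; events
before t weighted by 1/G(T-), patients still at risk by 1/G(t), patients
censored before t contributing zero).  Following the score over a time
grid gives a prediction error curve; competing Cox models are compared by
their mean out-of-bag curves over bootstrap resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, GenotypeMatrix
from .stability import dosage_matrix
from .survival import build_design, censoring_km, cox_fit, km

__all__ = ["ModelSpec", "PredictionErrorCurve", "ipcw_brier", "pec_compare", "integrated_brier"]

log = logging.getLogger(__name__)


def ipcw_brier(predicted_survival_at_t, time, event, t: float) -> float:
    """Inverse-probability-of-censoring-weighted Brier score at time ``t``.

    ``predicted_survival_at_t`` gives each patient's predicted P(T > t).
    Raises if the censoring survival G vanishes where a weight is needed
    (horizon beyond reliable follow-up).
    """
    pred = np.asarray(predicted_survival_at_t, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if ((pred < 0) | (pred > 1)).any():
        raise ValueError("predictions must be in [0, 1]")
    G = censoring_km(time, event)
    g_at_t = float(G.survival_at(t)[0])
    g_at_Ti = G.survival_at(time, left=True)  # G(T_i-)

    died = (time <= t) & (event == 1)
    at_risk = time > t
    censored_by_t = (time <= t) & (event == 0)
    if g_at_t <= 0 and (at_risk.any() or censored_by_t.any()):
        raise ValueError(
            f"censoring survival G is zero at t={t} (horizon beyond reliable "
            "follow-up); Brier score undefined"
        )
    if died.any() and (g_at_Ti[died] <= 0).any():
        raise ValueError(f"censoring survival G vanishes before a death time <= {t}")
    contrib = np.zeros(time.size)
    contrib[died] = pred[died] ** 2 / g_at_Ti[died]
    contrib[at_risk] = (1.0 - pred[at_risk]) ** 2 / g_at_t
    return float(contrib.mean())


@dataclass(frozen=True)
class ModelSpec:
    """A competing survival model: clinical covariates plus additive SNPs.

    ``null=True`` ignores both lists and predicts the marginal (in-bag)
    Kaplan-Meier survival for everyone.
    """

    label: str
    covariates: tuple[str, ...] = ()
    snp_ids: tuple[str, ...] = ()
    null: bool = False


@dataclass
class PredictionErrorCurve:
    """Mean out-of-bag IPCW Brier per model over a common time grid."""

    times: np.ndarray
    scores: pd.DataFrame     # index = model label, columns = times
    bootstrap_B: int
    n_skipped: int

    def to_tsv(self, path) -> None:
        long = self.scores.reset_index(names="model").melt(
            id_vars="model", var_name="time", value_name="brier"
        )
        long.to_csv(path, sep="\t", index=False)


def _model_design(spec: ModelSpec, clinical: ClinicalTable, gm: GenotypeMatrix):
    blocks = []
    names: list[str] = []
    if spec.covariates:
        d = build_design(clinical, list(spec.covariates))
        blocks.append(d.to_numpy(float))
        names += list(d.columns)
    if spec.snp_ids:
        X = dosage_matrix(gm.subset(snp_ids=list(spec.snp_ids)))
        blocks.append(X)
        names += list(spec.snp_ids)
    if not blocks:
        raise ValueError(f"model {spec.label!r}: no covariates and not null")
    return np.column_stack(blocks), names


def pec_compare(
    model_specs: list[ModelSpec],
    gm: GenotypeMatrix,
    clinical: ClinicalTable,
    endpoint: str = "pfs",
    time_grid=None,
    bootstrap_B: int = 100,
    seed: int = 0,
    max_skip_fraction: float = 0.10,
) -> PredictionErrorCurve:
    """Bootstrapped out-of-bag prediction error curves for competing models.

    Each resample draws n patients with replacement; every model is fit on
    the in-bag patients and scored by ``ipcw_brier`` on the out-of-bag
    patients over the grid (in-bag and out-of-bag index sets are disjoint
    by construction).  A resample where any model fails to fit is skipped
    and logged; more than ``max_skip_fraction`` skips is an error.  The
    marginal Kaplan-Meier model is prepended if no null model was given.
    """
    if not any(s.null for s in model_specs):
        model_specs = [ModelSpec("null", null=True)] + list(model_specs)
    time, event = clinical.endpoint(endpoint)
    n = time.size
    if time_grid is None:
        horizon = np.quantile(time[event == 1], 0.8) if (event == 1).any() else time.max()
        time_grid = np.linspace(0, horizon, 25)
    time_grid = np.asarray(time_grid, dtype=float)

    designs = {
        s.label: (None if s.null else _model_design(s, clinical, gm)) for s in model_specs
    }
    rng = np.random.default_rng(seed)
    acc = {s.label: np.zeros(time_grid.size) for s in model_specs}
    n_ok = 0
    n_skipped = 0
    for b in range(bootstrap_B):
        inbag = rng.choice(n, size=n, replace=True)
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size < 5 or event[inbag].sum() < 1 or event[oob].sum() < 1:
            n_skipped += 1
            continue
        try:
            curves = {}
            for s in model_specs:
                if s.null:
                    fit_km = km(time[inbag], event[inbag])
                    surv = np.tile(fit_km.survival_at(time_grid), (oob.size, 1))
                else:
                    X, _names = designs[s.label]
                    f = cox_fit(X[inbag], time[inbag], event[inbag],
                                keep_baseline=True)
                    surv = f.predict_survival(X[oob], time_grid)
                curves[s.label] = np.array([
                    ipcw_brier(surv[:, k], time[oob], event[oob], t)
                    for k, t in enumerate(time_grid)
                ])
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_skipped += 1
            log.warning("pec bootstrap %d skipped: %s", b, exc)
            continue
        for lbl, c in curves.items():
            acc[lbl] += c
        n_ok += 1
    if bootstrap_B and n_skipped / bootstrap_B > max_skip_fraction:
        raise RuntimeError(
            f"{n_skipped}/{bootstrap_B} bootstrap resamples skipped "
            f"(> {max_skip_fraction:.0%})"
        )
    if n_ok == 0:
        raise RuntimeError("no successful bootstrap resamples")
    scores = pd.DataFrame(
        {lbl: v / n_ok for lbl, v in acc.items()}, index=time_grid
    ).T
    return PredictionErrorCurve(time_grid, scores, bootstrap_B, n_skipped)


def integrated_brier(curve: PredictionErrorCurve, model: str) -> float:
    """Trapezoidal integral of one model's curve over its time grid."""
    y = curve.scores.loc[model].to_numpy(float)
    return float(np.trapezoid(y, curve.times) / (curve.times[-1] - curve.times[0]))
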