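"""Kaplan-Meier, log-rank and Cox partial-likelihood machinery."""

import numpy as np
import pytest

from snpsurv.io import encode
from snpsurv.survival import cox_fit, genotype_association, km, logrank

from conftest import make_clinical, make_gm


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 80)
        c = km(t, np.ones(80, dtype=int))
        for u, s in zip(c.times, c.survival):
            assert s == pytest.approx((t > u).mean(), abs=1e-12)

    def test_hand_computed_product_limit(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, S(2)=2/3, S(3)=0
        c = km([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 2 / 3, 0.0], atol=1e-12)

    def test_single_patient(self):
        c = km([5.0], [1])
        assert c.survival_at(4.9)[0] == 1.0
        assert c.survival_at(5.0)[0] == 0.0
        assert c.median == 5.0

    def test_matches_lifelines_with_censoring(self, small_survival):
        from lifelines import KaplanMeierFitter

        _, t, e = small_survival
        c = km(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = c.survival
        theirs = kmf.survival_function_.loc[c.times, "KM_estimate"].to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert c.median == pytest.approx(kmf.median_survival_time_)

    def test_all_missing_times_error(self):
        with pytest.raises(ValueError):
            km([np.nan, np.nan], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, df, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_three_groups_two_df(self):
        rng = np.random.default_rng(2)
        stat, df, p = logrank(rng.exponential(5, 60), np.ones(60, int),
                              rng.integers(0, 3, 60))
        assert df == 2

    def test_separated_groups_tiny_p(self):
        t = np.concatenate([np.arange(1, 21), np.arange(100, 120)])
        e = np.ones(40, int)
        g = np.repeat([0, 1], 20)
        _, _, p = logrank(t, e, g)
        assert p < 1e-4

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], [0, 0])

    def test_matches_lifelines(self, small_survival):
        from lifelines.statistics import multivariate_logrank_test

        x, t, e = small_survival
        stat, df, p = logrank(t, e, x)
        r = multivariate_logrank_test(t, x, e)
        assert stat == pytest.approx(r.test_statistic, rel=1e-9)
        assert p == pytest.approx(r.p_value, rel=1e-9)

    def test_two_group_logrank_equals_cox_score_test(self):
        # classical identity (no ties, Breslow): log-rank == score test of
        # the group indicator at beta = 0
        rng = np.random.default_rng(5)
        n = 60
        t = rng.permutation(np.arange(1, n + 1)).astype(float)  # no ties
        e = np.ones(n, int)
        g = rng.integers(0, 2, n)
        stat, _, _ = logrank(t, e, g)
        from snpsurv.survival import _cox_loglik_grad_hess

        X = g[:, None].astype(float)
        _, grad, info = _cox_loglik_grad_hess(X, t, e, np.zeros(1), "breslow")
        score_stat = grad[0] ** 2 / info[0, 0]
        assert stat == pytest.approx(score_stat, abs=1e-6)


def grid_search_cox_beta(x, time, event, lo=-3, hi=3):
    """Independent oracle: maximise the explicit partial likelihood on a grid."""
    x = np.asarray(x, float)
    order = np.argsort(time)
    x, event = x[order], np.asarray(event)[order]

    def ll(b):
        eta = b * x
        r = np.exp(eta)
        s = np.cumsum(r[::-1])[::-1]
        return sum(eta[i] - np.log(s[i]) for i in range(len(x)) if event[i])

    grid = np.linspace(lo, hi, 2001)
    b = grid[np.argmax([ll(v) for v in grid])]
    for _ in range(40):  # ternary refinement
        lo_, hi_ = b - (grid[1] - grid[0]), b + (grid[1] - grid[0])
        grid = np.linspace(lo_, hi_, 201)
        b = grid[np.argmax([ll(v) for v in grid])]
    return b


class TestCoxFit:
    def test_symmetric_design_gives_zero_beta(self):
        # duplicated data with the group label swapped: by symmetry beta = 0
        t = np.array([3.0, 5, 7, 9, 3, 5, 7, 9])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0.0, 1, 0, 1, 1, 0, 1, 0])
        f = cox_fit(x, t, e)
        assert f.beta[0] == pytest.approx(0.0, abs=1e-9)
        assert f.hazard_ratios[0] == pytest.approx(1.0, abs=1e-8)

    def test_eight_patient_grid_search_oracle(self):
        t = np.array([2.0, 5, 6, 9, 11, 14, 17, 20])  # no ties
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([0.3, -1.2, 0.8, 1.5, -0.4, 0.0, 2.1, -0.9])
        f = cox_fit(x, t, e, ties="breslow")
        oracle = grid_search_cox_beta(x, t, e)
        assert f.beta[0] == pytest.approx(oracle, abs=1e-6)

    def test_efron_equals_breslow_without_ties(self, small_survival):
        x, t, e = small_survival
        t = t + np.linspace(0, 1e-4, t.size)  # break the rounding ties
        fe = cox_fit(x, t, e, ties="efron")
        fb = cox_fit(x, t, e, ties="breslow")
        np.testing.assert_allclose(fe.beta, fb.beta, atol=1e-10)
        np.testing.assert_allclose(fe.loglik, fb.loglik, atol=1e-8)

    def test_score_at_solution_vanishes(self, small_survival):
        from snpsurv.survival import _cox_loglik_grad_hess

        x, t, e = small_survival
        f = cox_fit(x, t, e)
        _, grad, _ = _cox_loglik_grad_hess(x[:, None], t, e, f.beta, "efron")
        assert np.abs(grad).max() < 1e-8

    def test_matches_lifelines_multivariable(self, small_survival):
        from lifelines import CoxPHFitter
        import pandas as pd

        x, t, e = small_survival
        rng = np.random.default_rng(0)
        z = rng.normal(size=x.size)
        f = cox_fit(np.column_stack([x, z]), t, e)
        df = pd.DataFrame({"x": x, "z": z, "t": t, "e": e})
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(f.beta, ll.params_.values, atol=1e-6)
        np.testing.assert_allclose(f.se, ll.standard_errors_.values, atol=1e-6)

    def test_duplicated_columns_rejected(self):
        t = np.arange(1.0, 11)
        e = np.ones(10, int)
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(np.column_stack([x, x]), t, e)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones(10), np.arange(1.0, 11), np.ones(10, int))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(np.arange(5.0), np.arange(1.0, 6), np.zeros(5, int))

    def test_separation_flagged_not_silent(self):
        # perfectly separating covariate: monotone likelihood
        t = np.arange(1.0, 21)
        e = np.ones(20, int)
        x = (t > 10).astype(float)
        with pytest.warns(UserWarning, match="converge"):
            f = cox_fit(x, t, e)
        assert not f.converged

    def test_stratified_fit_uses_within_stratum_risk_sets(self):
        # shift all times in one stratum by a constant: stratified partial
        # likelihood is invariant to within-stratum monotone time changes
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = np.ones(100, int)
        s = (np.arange(100) < 50).astype(int)
        f1 = cox_fit(x, t, e, strata=s)
        t2 = t.copy()
        t2[s == 1] = t2[s == 1] * 3 + 100
        f2 = cox_fit(x, t2, e, strata=s)
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-9)


class TestGenotypeAssociation:
    def test_recovers_planted_dominant_effect(self, planted_cohort):
        gm, ct = planted_cohort
        rec = genotype_association(gm, "rs0", "dominant", ct, ["sex", "age"])
        assert rec.estimable
        assert rec.wald_df == 1
        assert rec.ci_lower[0] < 2.0 < rec.ci_upper[0]

    def test_codominant_is_two_df(self, planted_cohort):
        gm, ct = planted_cohort
        rec = genotype_association(gm, "rs0", "codominant", ct, ["sex", "age"])
        assert rec.wald_df == 2
        assert rec.contrast_names == ["het", "hom_minor"]
        assert set(rec.group_sizes) == {"hom_major", "het", "hom_minor"}

    def test_missing_genotypes_excluded(self, planted_cohort):
        gm, ct = planted_cohort
        from snpsurv.io import GenotypeMatrix

        codes = gm.codes.copy()
        codes[:10, 0] = np.nan
        gm2 = GenotypeMatrix(gm.patient_ids, gm.snps.copy(), codes)
        rec = genotype_association(gm2, "rs0", "dominant", ct, [])
        assert rec.n_used == gm.n_patients - 10

    def test_empty_group_flagged_inestimable(self):
        gm = make_gm(np.array([[0.0], [1], [0], [1], [0], [1]]))  # no hom-minor
        ct = make_clinical([5, 6, 7, 8, 9, 10], [1, 1, 1, 1, 0, 1], gm)
        rec = genotype_association(gm, "rs0", "recessive", ct, [])
        assert not rec.estimable
        assert "empty genotype group" in rec.message
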